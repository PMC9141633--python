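"""End-to-end orchestration: cohort -> FC matrices -> graph-level analyses.

Each stage reads and writes delimited-text tables, stamps its outputs with
the hash of the configuration that produced them, and derives every random
seed from a single run seed, so reruns with the same config are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .inference import build_null, performance, scenario_performance
from .measures import MEASURES, compute_measure
from .network import (
    FCMatrix,
    measure_similarity,
    nonrandomness,
    partition_edges,
    subject_similarity,
)
from .simulate import REGIMES, SCENARIOS, ScenarioSpec, simulate_pair

__all__ = ["run_fc", "run_bench", "run_analyze", "run_simulate"]


def run_simulate(
    out_dir: Path, scenario: str, regime: str, reps: int, seed: int, **spec_kwargs
) -> pd.DataFrame:
    """Write ``reps`` simulated region pairs as delimited matrices + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        spec = ScenarioSpec(
            scenario=scenario,
            regime=regime,
            seed=int(root.integers(0, 2**31 - 1)),
            **spec_kwargs,
        )
        pair = simulate_pair(spec)
        for region in (pair.region_x, pair.region_y):
            fname = f"rep{rep:03d}_{region.region_id}.tsv"
            io.write_region(region, out_dir / fname)
            rows.append(
                {
                    "subject": f"rep{rep:03d}",
                    "region": region.region_id,
                    "file": fname,
                    "scenario": scenario,
                    "regime": regime,
                    "seed": spec.seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / io.MANIFEST_NAME, sep="\t", index=False)
    io.write_provenance(
        out_dir, "simulate",
        {"scenario": scenario, "regime": regime, "reps": reps, "seed": seed, **spec_kwargs},
    )
    return manifest


def run_fc(
    manifest_path: Path, out_dir: Path, measure: str, n_components: int = 5
) -> list[Path]:
    """Compute one FC matrix per subject in a manifest; write as TSV."""
    from .network import assemble_fc

    subjects = io.read_manifest(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kwargs = {"n_components": n_components} if measure == "mvmi" else {}
    written = []
    for subject_id, regions in subjects.items():
        fc = assemble_fc(regions, measure, subject_id=subject_id, **kwargs)
        path = out_dir / f"fc_{measure}_{subject_id}.tsv"
        io.write_fc_matrix(fc, path)
        written.append(path)
    io.write_provenance(
        out_dir, "fc",
        {"manifest": str(manifest_path), "measure": measure, "n_components": n_components},
    )
    return written


def run_bench(
    out_path: Path | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
    regimes: tuple[str, ...] = REGIMES,
    measures: tuple[str, ...] = tuple(MEASURES),
    reps: int = 20,
    n_perm: int = 100,
    seed: int = 0,
    **spec_kwargs,
) -> pd.DataFrame:
    """Scenario x regime x measure benchmark table (mean/sd performance)."""
    rows = []
    for scenario in scenarios:
        for regime in regimes:
            spec = ScenarioSpec(scenario=scenario, regime=regime, **spec_kwargs)
            for measure in measures:
                mean, sd = scenario_performance(
                    spec, measure, reps=reps, n_perm=n_perm, seed=seed
                )
                rows.append(
                    {
                        "scenario": scenario,
                        "regime": regime,
                        "measure": measure,
                        "reps": reps,
                        "n_perm": n_perm,
                        "mean_performance": mean,
                        "sd_performance": sd,
                    }
                )
    table = pd.DataFrame(rows)
    digest = io.config_hash(
        {"scenarios": scenarios, "regimes": regimes, "measures": measures,
         "reps": reps, "n_perm": n_perm, "seed": seed, **spec_kwargs}
    )
    table["config_hash"] = digest
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


def run_analyze(
    cohort_dir: Path,
    out_dir: Path,
    measures: tuple[str, ...] = ("pcor", "uvmi", "mvmi"),
    n_perm: int = 100,
    density: float = 0.10,
    k: int = 7,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Graph-level comparison of measures on a cohort directory.

    Produces tidy tables: per-subject/measure significant-edge counts split
    within/between network, pairwise measure similarity (rank correlation),
    nonrandomness totals, and between-subject similarity.
    """
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = io.read_manifest(cohort_dir / io.MANIFEST_NAME)
    assign = io.read_assignment(cohort_dir / io.ASSIGNMENT_NAME)
    root = np.random.default_rng(seed)

    from .network import assemble_fc

    fcs: dict[str, dict[str, FCMatrix]] = {m: {} for m in measures}
    sig_rows, nonrand_rows = [], []
    for subject_id, regions in sorted(subjects.items()):
        for measure in measures:
            fc = assemble_fc(regions, measure, subject_id=subject_id)
            fcs[measure][subject_id] = fc
            edge_class = partition_edges(fc, assign)
            counts = {"within": [0, 0], "between": [0, 0]}  # [significant, total]
            for cls, edges in (("within", edge_class.within), ("between", edge_class.between)):
                for i, j in edges:
                    null = build_null(
                        regions[i], regions[j], measure,
                        n_perm=n_perm, seed=int(root.integers(0, 2**31 - 1)),
                    )
                    verdict = performance(fc.values[i, j], null)
                    counts[cls][0] += int(verdict.significant)
                    counts[cls][1] += 1
            for cls, (n_sig, n_tot) in counts.items():
                sig_rows.append(
                    {
                        "subject": subject_id,
                        "measure": measure,
                        "edge_class": cls,
                        "n_significant": n_sig,
                        "n_edges": n_tot,
                    }
                )
            total, _ = nonrandomness(fc, density=density, k=k)
            nonrand_rows.append(
                {"subject": subject_id, "measure": measure, "density": density,
                 "k": k, "nonrandomness": total}
            )

    sim_rows = []
    subject_ids = sorted(next(iter(fcs.values())))
    for a_i, m_a in enumerate(measures):
        for m_b in measures[a_i + 1 :]:
            vals = [
                measure_similarity(fcs[m_a][s], fcs[m_b][s]) for s in subject_ids
            ]
            sim_rows.append(
                {"measure_a": m_a, "measure_b": m_b,
                 "mean_rank_correlation": float(np.mean(vals))}
            )

    subj_rows = []
    for measure in measures:
        sims = subject_similarity([fcs[measure][s] for s in subject_ids])
        for s, val in zip(subject_ids, sims):
            subj_rows.append({"subject": s, "measure": measure, "similarity": float(val)})

    tables = {
        "significance": pd.DataFrame(sig_rows),
        "nonrandomness": pd.DataFrame(nonrand_rows),
        "measure_similarity": pd.DataFrame(sim_rows),
        "subject_similarity": pd.DataFrame(subj_rows),
    }
    digest = io.write_provenance(
        out_dir, "analyze",
        {"cohort_dir": str(cohort_dir), "measures": measures, "n_perm": n_perm,
         "density": density, "k": k, "seed": seed},
    )
    for name, table in tables.items():
        table["config_hash"] = digest
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return tables
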