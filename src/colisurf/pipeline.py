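"""End-to-end orchestration: simulate → fingerprint → assays → stats.

Each stage reads and writes plain-text files in the run directory, records
SHA-256 hashes of its outputs in a machine-readable manifest, and the whole
run is byte-reproducible given the same configuration.  A stage failure is
recorded in the manifest and downstream stages are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, cohort as cohort_mod, fingerprint, stats

__all__ = ["RunConfig", "RunManifest", "run_all", "demo_config"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    outdir: str
    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    input_dir: str | None = None  # pre-existing cohort directory instead of simulation
    tolerance: float = 0.005
    optimization: float = 0.005
    distinct_threshold: float = 0.90
    n_perm: int = 9999
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cc = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cc is not None:
            if "titration_model" in cc:
                cc["titration_model"] = tuple(tuple(s) for s in cc["titration_model"])
            if "eps_cells_range" in cc:
                cc["eps_cells_range"] = tuple(cc["eps_cells_range"])
            cfg.cohort = cohort_mod.CohortConfig(**cc)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.as_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    dropped_strains: list = field(default_factory=list)
    ok: bool = True

    def record(self, name: str, status: str, outputs: dict[str, str], seconds: float,
               detail: str | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "status": status,
                "outputs": outputs,
                "wall_seconds": round(seconds, 3),
                "detail": detail,
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hashes(paths: dict[str, Path]) -> dict[str, str]:
    return {k: _sha256(Path(p)) for k, p in paths.items()}


def _jsonable(obj):
    """Recursively convert a report to JSON-safe types (NaN -> null)."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_all(config: RunConfig) -> RunManifest:
    """Execute all four stages; return the manifest (also written to disk).

    Strains dropped at any stage (no usable bands, degenerate assays) are
    listed with reasons.  On a stage failure the manifest marks the failure
    and the remaining stages are skipped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["cohort"] = config.cohort.as_dict()
    manifest = RunManifest(config=cfg_dict)

    def fail(stage: str, t0: float, exc: Exception) -> RunManifest:
        manifest.record(stage, "failed", {}, time.perf_counter() - t0, detail=str(exc))
        manifest.ok = False
        manifest.write(outdir / "manifest.json")
        return manifest

    # --- stage 1: cohort -------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.input_dir is not None:
            cohort_dir = Path(config.input_dir)
            paths = {
                k: cohort_dir / f"{k}.csv"
                for k in ("strains", "profiles", "titrations", "standards")
            }
            missing = [str(p) for p in paths.values() if not p.exists()]
            if missing:
                raise FileNotFoundError(f"cohort inputs missing: {missing}")
        else:
            synthetic = cohort_mod.generate_cohort(config.cohort)
            cohort_dir = outdir / "cohort"
            paths = cohort_mod.write_cohort(synthetic, cohort_dir)
    except Exception as exc:
        return fail("simulate", t0, exc)
    manifest.record("simulate", "completed", _hashes(paths), time.perf_counter() - t0)

    # --- stage 2: fingerprint -------------------------------------------
    t0 = time.perf_counter()
    try:
        profiles = cohort_mod.read_profiles(cohort_dir)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sim = fingerprint.similarity_matrix(
                profiles, tolerance=config.tolerance, optimization=config.optimization
            )
        for w in caught:
            manifest.dropped_strains.append({"stage": "fingerprint", "reason": str(w.message)})
        dropped = sorted(set(p.strain_id for p in profiles) - set(sim.labels))
        tree = fingerprint.upgma(sim)
        reps = fingerprint.select_distinct(sim, threshold=config.distinct_threshold)
        sim_path = outdir / "similarity.csv"
        sim.to_csv(sim_path)
        nwk_path = outdir / "dendrogram.nwk"
        nwk_path.write_text(tree.to_newick() + "\n")
        reps_path = outdir / "representatives.txt"
        reps_path.write_text("\n".join(reps) + "\n")
        strain_meta = pd.read_csv(cohort_dir / "strains.csv")
        phylo_path = outdir / "phylotypes.csv"
        pd.DataFrame(
            {
                "strain_id": strain_meta["strain_id"],
                "phylotype": [
                    fingerprint.assign_phylotype(
                        fingerprint.MarkerProfile(
                            arpA=bool(row.arpA), chuA=bool(row.chuA),
                            yjaA=bool(row.yjaA), tspE4=bool(row.tspE4),
                            group_c=row.group_c, group_e=row.group_e,
                        )
                    )
                    for row in strain_meta.itertuples()
                ],
            }
        ).to_csv(phylo_path, index=False)
    except Exception as exc:
        return fail("fingerprint", t0, exc)
    manifest.record(
        "fingerprint",
        "completed",
        _hashes({"similarity": sim_path, "dendrogram": nwk_path,
                 "representatives": reps_path, "phylotypes": phylo_path}),
        time.perf_counter() - t0,
        detail=f"{len(sim)} strains, {len(reps)} distinct genotypes" + (
            f", dropped {dropped}" if dropped else ""),
    )

    # --- stage 3: assays --------------------------------------------------
    t0 = time.perf_counter()
    try:
        data = cohort_mod.read_cohort(cohort_dir, require_profiles=False)
        kept = [r for r in data.records if r.strain_id in set(sim.labels)]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = assays.build_property_table(
                kept, data.blank, data.protein_curve, data.sugar_curve
            )
        for w in caught:
            manifest.dropped_strains.append({"stage": "assays", "reason": str(w.message)})
        prop_path = outdir / "properties.csv"
        table.to_csv(prop_path)
    except Exception as exc:
        return fail("assays", t0, exc)
    manifest.record("assays", "completed", _hashes({"properties": prop_path}),
                    time.perf_counter() - t0)

    # --- stage 4: stats ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        report = stats.habitat_report(
            table, sim, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha
        )
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(_jsonable(report), indent=1))
        corr = report["correlations"]["all"]
        table1 = pd.DataFrame(corr["tau"], index=corr["properties"], columns=corr["properties"])
        table1_path = outdir / "table1.csv"
        table1.to_csv(table1_path, index_label="property")
        fig3_rows = []
        for prop, entry in report["properties"].items():
            for hab in ("sediment", "water"):
                if hab in entry:
                    fig3_rows.append({"property": prop, "habitat": hab, **{
                        k: v for k, v in entry[hab].items() if k != "outliers"}})
        fig3_path = outdir / "figure3_summary.csv"
        pd.DataFrame(fig3_rows).to_csv(fig3_path, index=False)
        fig4_path = outdir / "figure4_data.csv"
        table[["habitat", "hydrophobicity", "eps_protein"]].to_csv(fig4_path)
    except Exception as exc:
        return fail("stats", t0, exc)
    manifest.record(
        "stats",
        "completed",
        _hashes({"report": report_path, "table1": table1_path,
                 "figure3_summary": fig3_path, "figure4_data": fig4_path}),
        time.perf_counter() - t0,
    )

    manifest.write(outdir / "manifest.json")
    return manifest


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """A small 12+12 cohort that runs end-to-end in seconds."""
    cc = cohort_mod.CohortConfig(n_sediment=12, n_water=12, seed=seed)
    return RunConfig(outdir=outdir, cohort=cc, n_perm=999, seed=seed)
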