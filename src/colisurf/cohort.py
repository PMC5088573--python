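"""Synthetic strain cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: two
habitat groups (stream sediment, stream water) whose fingerprint band pools
overlap partially — so genomic similarity is larger within habitat than
between — and surface-property traits built as

    y = mu + beta * 1{sediment} + g + eps,

where g is a genome-correlated random effect with covariance
sigma_g^2 * V (V the realized fingerprint similarity matrix after SPD
repair) and eps is iid measurement noise.  Raw assay data (MATH optical
densities, titration records, EPS absorbances) are back-computed from the
true trait values through the same closed-form models the assay module
inverts, so a noise-free cohort round-trips exactly and every latent value
is recorded in a :class:`TruthBundle`.

The titration model is a multi-site Henderson-Hasselbalch surface:

    q(pH) = offset − sum_i d_i / (1 + 10^(pKa_i − pH))    [meq / 10^8 cells]

with per-strain site densities scaled by exp(charge_factor), a latent trait
that simultaneously moves total acidity (down), net charge at pH 8 (less
negative) and the point of zero charge (up) — the coupled directions seen
between the two habitats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import PKW, StandardCurve, TitrationCurve, _proton_hydroxide_mmol
from .fingerprint import BandProfile, MarkerProfile, SimilarityMatrix, similarity_matrix
from .stats import similarity_to_covariance

__all__ = [
    "CohortConfig",
    "StrainRecord",
    "TruthBundle",
    "SyntheticCohort",
    "model_net_charge",
    "titration_curve_from_model",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "read_profiles",
]

#: Latent traits that receive a direct habitat effect.
LATENT_TRAITS = ["hydrophobicity", "zeta_potential", "eps_protein", "eps_sugar", "charge_factor"]

# Quadruplex genotypes used when synthesizing marker profiles per phylotype.
_PHYLOTYPE_GENOTYPE = {
    "A": dict(arpA=True, chuA=False, yjaA=False, tspE4=False),
    "B1": dict(arpA=True, chuA=False, yjaA=False, tspE4=True),
    "B2": dict(arpA=False, chuA=True, yjaA=True, tspE4=False),
    "F": dict(arpA=False, chuA=True, yjaA=False, tspE4=False),
    "A/C": dict(arpA=True, chuA=True, yjaA=False, tspE4=False),
    "D/E": dict(arpA=True, chuA=True, yjaA=True, tspE4=False),
    "E": dict(arpA=True, chuA=True, yjaA=True, tspE4=False, group_e="positive"),
    "unknown": dict(arpA=False, chuA=False, yjaA=False, tspE4=False),
}

# Habitat-specific phylotype frequencies used for synthetic marker profiles
# (sediment isolates are the more diverse group; water is B1-dominated).
_PHYLOTYPE_FREQS = {
    "sediment": (("D/E", 0.25), ("B1", 0.23), ("B2", 0.20), ("A/C", 0.16), ("A", 0.11),
                 ("E", 0.02), ("F", 0.02), ("unknown", 0.01)),
    "water": (("B1", 0.56), ("D/E", 0.19), ("A", 0.09), ("A/C", 0.09), ("E", 0.03),
              ("F", 0.03), ("unknown", 0.01)),
}


def _default_habitat_effects() -> dict:
    return {
        "hydrophobicity": 0.15,
        "zeta_potential": 0.0,
        "eps_protein": 0.08,
        "eps_sugar": 0.12,
        "charge_factor": -0.35,
    }


def _default_means() -> dict:
    return {
        "hydrophobicity": 0.35,
        "zeta_potential": -20.0,
        "eps_protein": 0.55,
        "eps_sugar": 1.25,
        "charge_factor": 0.0,
    }


def _default_scales() -> dict:
    return {
        "hydrophobicity": 1.0,
        "zeta_potential": 60.0,
        "eps_protein": 1.0,
        "eps_sugar": 1.6,
        "charge_factor": 1.0,
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults mirror the study design.

    Group sizes default to 44 sediment + 33 water strains.  Site densities
    are in meq per 10^8 cells; habitat effects are on each trait's own scale
    (``charge_factor`` is the log of the per-strain titratable-site scaling).
    """

    n_sediment: int = 44
    n_water: int = 33
    n_band_positions: int = 30
    shared_band_fraction: float = 0.9
    habitat_effects: dict = field(default_factory=_default_habitat_effects)
    genomic_sd: float = 0.1
    residual_sd: float = 0.05
    titration_model: tuple = ((1.2e-4, 5.0), (8.0e-5, 8.5))
    charge_offset: float = 9.0e-5
    seed: int = 0
    # secondary knobs
    property_means: dict = field(default_factory=_default_means)
    property_scales: dict = field(default_factory=_default_scales)
    sediment_coupling: float = 0.75  # hydrophobicity -> EPS-protein slope, sediment only
    band_presence_prob: float = 0.75
    intensity_sigma: float = 0.35
    band_jitter: float = 0.003  # per-band position jitter, fraction of the log-size span
    noise_band_rate: float = 12.0  # mean count of lane-specific spurious bands (Poisson)
    noise_band_intensity: float = 1.0  # median intensity of spurious bands vs real bands
    ph_step: float = 0.05
    titration_noise_sd: float = 0.0  # iid pH measurement noise (pH units)
    n_bact: float = 1.0e8  # cells/mL in the titrated suspension
    c_acid0: float = 0.5  # initial acid in the titration vessel, mmol/L
    math_initial_od: float = 0.4
    eps_cells_range: tuple = (3.0e10, 6.0e10)

    def __post_init__(self) -> None:
        if min(self.n_sediment, self.n_water, self.n_band_positions) < 2:
            raise ValueError("all counts must be at least 2")
        if not 0.0 <= self.shared_band_fraction <= 1.0:
            raise ValueError("shared_band_fraction must be in [0, 1]")
        if min(self.genomic_sd, self.residual_sd, self.titration_noise_sd, self.band_jitter) < 0:
            raise ValueError("standard deviations must be non-negative")
        for density, pka in self.titration_model:
            if density < 0:
                raise ValueError("site densities must be non-negative")
            if not 4.0 < pka < 10.0:
                raise ValueError("site pKa values must lie strictly inside the (4, 10) window")
        if not 0.0 < self.band_presence_prob <= 1.0:
            raise ValueError("band_presence_prob must be in (0, 1]")
        for name in LATENT_TRAITS:
            if name not in self.habitat_effects:
                self.habitat_effects[name] = 0.0
            if name not in self.property_means or name not in self.property_scales:
                raise ValueError(f"means/scales must cover latent trait {name!r}")
            if self.property_scales[name] <= 0:
                raise ValueError("property scales must be positive")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["titration_model"] = [list(s) for s in self.titration_model]
        d["eps_cells_range"] = list(self.eps_cells_range)
        return d


@dataclass
class StrainRecord:
    """One strain: identity, habitat, fingerprint, markers and raw assay data."""

    strain_id: str
    habitat: str
    profile: BandProfile
    markers: MarkerProfile
    math_reading: tuple  # (initial OD546, aqueous-phase OD546)
    zeta_potential: float
    titration: TitrationCurve
    eps_absorbances: tuple  # (protein absorbance, sugar absorbance)
    eps_n_cells: float
    true_traits: dict | None = None

    def __post_init__(self) -> None:
        if self.habitat not in ("sediment", "water"):
            raise ValueError("habitat must be 'sediment' or 'water'")
        if self.math_reading[0] <= 0 or self.math_reading[1] < 0:
            raise ValueError("MATH optical densities must be positive")


@dataclass
class TruthBundle:
    """Ground truth of a synthetic cohort: every latent the generator drew."""

    config: CohortConfig
    properties: pd.DataFrame  # strains x (habitat + 8 true property values)
    latent_genomic: pd.DataFrame  # g per latent trait (unscaled)
    latent_residual: pd.DataFrame  # eps per latent trait (unscaled)
    similarity: SimilarityMatrix  # realized fingerprint similarity
    covariance: np.ndarray  # SPD repair of the similarity matrix
    charge_scale: pd.Series  # per-strain exp(charge_factor)


@dataclass
class SyntheticCohort:
    """Records plus the shared calibration objects the assays need."""

    records: list
    blank: TitrationCurve
    protein_curve: StandardCurve
    sugar_curve: StandardCurve
    truth: TruthBundle | None = None


# ---------------------------------------------------------------------------
# Titration model


def model_net_charge(ph, sites: Sequence[tuple], offset: float = 0.0):
    """Closed-form net charge of a multi-site protonation model (meq/1e8 cells)."""
    ph = np.asarray(ph, dtype=float)
    q = np.full(ph.shape, float(offset))
    for density, pka in sites:
        q = q - density / (1.0 + 10.0 ** (pka - ph))
    return q


def titration_curve_from_model(
    sites: Sequence[tuple],
    ph_grid: Sequence[float],
    n_bact: float,
    offset: float = 0.0,
    c_acid0: float = 0.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[TitrationCurve, TitrationCurve]:
    """Sample + blank titration records consistent with the charge model.

    Solves the inverse problem of the charge-accounting equation: cumulative
    base amounts are chosen so that blank-corrected charge accounting
    recovers exactly ``model_net_charge(ph, sites, offset)``.  The blank is
    a strong-acid/strong-base balance; the sample adds the surface term.
    ``noise_sd`` jitters the recorded pH values (measurement noise); the
    default 0 keeps recovery exact.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.ndim != 1 or ph.size < 2 or np.any(np.diff(ph) <= 0):
        raise ValueError("ph_grid must be strictly increasing")
    if n_bact <= 0:
        raise ValueError("n_bact must be positive")
    h, oh = _proton_hydroxide_mmol(ph)
    cb_blank = c_acid0 - h + oh
    q = model_net_charge(ph, sites, offset)
    cb_sample = cb_blank - q * (n_bact / 1e8) * 1e3
    if cb_blank.min() < -1e-12 or cb_sample.min() < -1e-12:
        raise ValueError("negative cumulative base; increase c_acid0 for this model")
    ph_rec = ph
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        ph_rec = np.sort(ph + rng.normal(0.0, noise_sd, ph.size))
    ca = np.full(ph.size, c_acid0)
    sample = TitrationCurve(ph_rec, ca, np.maximum(cb_sample, 0.0), role="sample", n_bact=n_bact)
    blank = TitrationCurve(ph, ca, np.maximum(cb_blank, 0.0), role="blank")
    return sample, blank


def _model_pzc(sites: Sequence[tuple], offset: float, lo: float = 4.0, hi: float = 10.0) -> float:
    """Analytic root of the closed-form charge model inside [lo, hi], or NaN."""
    from scipy.optimize import brentq

    qlo = float(model_net_charge(lo, sites, offset))
    qhi = float(model_net_charge(hi, sites, offset))
    if qlo == 0.0:
        return lo
    if qhi == 0.0:
        return hi
    if qlo * qhi > 0:
        return float("nan")
    return float(brentq(lambda p: float(model_net_charge(p, sites, offset)), lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_band_pools(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Habitat band pools: a shared core plus habitat-specific positions."""
    n_shared = int(round(cfg.shared_band_fraction * cfg.n_band_positions))
    n_spec = cfg.n_band_positions - n_shared
    total = n_shared + 2 * n_spec
    # log-uniform positions, kept away from the filter edges
    logpos = rng.uniform(np.log10(350.0), np.log10(4800.0), total)
    pos = 10.0 ** logpos
    shared = pos[:n_shared]
    sed = np.concatenate([shared, pos[n_shared : n_shared + n_spec]])
    wat = np.concatenate([shared, pos[n_shared + n_spec :]])
    return {"sediment": sed, "water": wat}


def _draw_profile(
    strain_id: str, pool: np.ndarray, cfg: CohortConfig, rng: np.random.Generator
) -> BandProfile:
    present = rng.random(pool.size) < cfg.band_presence_prob
    if not present.any():
        present[rng.integers(pool.size)] = True
    positions = pool[present]
    intensities = np.exp(rng.normal(0.0, cfg.intensity_sigma, positions.size))
    # lane-specific spurious bands (faint partial-amplification products and
    # gel artefacts); they give each lane an idiosyncratic component, which is
    # what keeps real similarity matrices comfortably positive definite
    n_noise = rng.poisson(cfg.noise_band_rate)
    if n_noise:
        noise_pos = 10.0 ** rng.uniform(np.log10(350.0), np.log10(4800.0), n_noise)
        noise_int = cfg.noise_band_intensity * np.exp(
            rng.normal(0.0, cfg.intensity_sigma, n_noise)
        )
        positions = np.concatenate([positions, noise_pos])
        intensities = np.concatenate([intensities, noise_int])
    # lane-to-lane migration noise: jitter each band's log-position slightly
    # (the reason densitometric comparison needs a band-matching tolerance)
    span = np.log10(5000.0) - np.log10(300.0)
    logpos = np.log10(positions) + rng.normal(0.0, cfg.band_jitter * span, positions.size)
    positions = np.clip(10.0 ** logpos, 310.0, 4950.0)
    order = np.argsort(positions)
    # keep positions strictly increasing even if jitter creates near-ties
    positions = np.maximum.accumulate(positions[order]) + np.arange(positions.size) * 1e-8
    return BandProfile(strain_id, positions, intensities[order])


def _draw_markers(habitat: str, rng: np.random.Generator) -> MarkerProfile:
    labels, weights = zip(*_PHYLOTYPE_FREQS[habitat])
    w = np.asarray(weights) / np.sum(weights)
    label = labels[rng.choice(len(labels), p=w)]
    return MarkerProfile(**_PHYLOTYPE_GENOTYPE[label])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given the config seed."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_pool, rng_band, rng_trait, rng_noise, rng_marker, rng_assay = (
        np.random.default_rng(s) for s in streams
    )

    n = cfg.n_sediment + cfg.n_water
    habitats = ["sediment"] * cfg.n_sediment + ["water"] * cfg.n_water
    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    pools = _draw_band_pools(cfg, rng_pool)
    profiles = [
        _draw_profile(sid, pools[hab], cfg, rng_band) for sid, hab in zip(ids, habitats)
    ]

    sim = similarity_matrix(profiles)
    if len(sim) != n:
        raise ValueError("degenerate configuration: strains lost during similarity analysis")
    v = similarity_to_covariance(sim)
    chol = np.linalg.cholesky(v)

    sed_ind = np.array([h == "sediment" for h in habitats], dtype=float)
    g = {}
    e = {}
    traits = {}
    for name in LATENT_TRAITS:
        g[name] = cfg.genomic_sd * (chol @ rng_trait.normal(size=n))
        e[name] = cfg.residual_sd * rng_noise.normal(size=n)
        traits[name] = (
            cfg.property_means[name]
            + cfg.habitat_effects[name] * sed_ind
            + cfg.property_scales[name] * (g[name] + e[name])
        )
    # sediment-only coupling: EPS protein tracks the hydrophobicity deviation
    hydro_dev = cfg.property_scales["hydrophobicity"] * (g["hydrophobicity"] + e["hydrophobicity"])
    traits["eps_protein"] = traits["eps_protein"] + cfg.sediment_coupling * sed_ind * hydro_dev

    hydro = np.clip(traits["hydrophobicity"], 0.01, 0.99)
    protein = np.maximum(traits["eps_protein"], 0.01)
    sugar = np.maximum(traits["eps_sugar"], 0.05)
    zeta = traits["zeta_potential"]
    a_scale = np.exp(traits["charge_factor"])

    ph_grid = np.round(np.arange(4.0, 10.0 + cfg.ph_step / 2, cfg.ph_step), 10)
    base_sites = list(cfg.titration_model)

    # shared calibration objects
    prot_conc = np.array([0.0, 50.0, 100.0, 200.0, 400.0])
    protein_curve = StandardCurve(prot_conc, 0.002 * prot_conc + 0.02)
    sugar_conc = np.array([0.0, 100.0, 200.0, 400.0, 800.0])
    sugar_curve = StandardCurve(sugar_conc, 0.0012 * sugar_conc + 0.01)
    _, blank = titration_curve_from_model([], ph_grid, 1.0, 0.0, cfg.c_acid0)

    records: list[StrainRecord] = []
    prop_rows = []
    for i, (sid, hab, prof) in enumerate(zip(ids, habitats, profiles)):
        sites = [(d * a_scale[i], pka) for d, pka in base_sites]
        sample, _ = titration_curve_from_model(
            sites,
            ph_grid,
            cfg.n_bact,
            offset=cfg.charge_offset,
            c_acid0=cfg.c_acid0,
            noise_sd=cfg.titration_noise_sd,
            rng=rng_assay,
        )
        q8 = float(model_net_charge(8.0, sites, cfg.charge_offset))
        acidity = float(
            model_net_charge(4.0, sites, cfg.charge_offset)
            - model_net_charge(10.0, sites, cfg.charge_offset)
        )
        pzc = _model_pzc(sites, cfg.charge_offset)
        n_cells = rng_assay.uniform(*cfg.eps_cells_range)
        prot_abs = protein_curve.slope * (protein[i] * n_cells / 1e8) + protein_curve.intercept
        sugar_abs = sugar_curve.slope * (sugar[i] * n_cells / 1e8) + sugar_curve.intercept
        true_props = {
            "hydrophobicity": float(hydro[i]),
            "zeta_potential": float(zeta[i]),
            "eps_protein": float(protein[i]),
            "eps_sugar": float(sugar[i]),
            "eps_ratio": float(protein[i] / sugar[i]),
            "net_charge_ph8": q8,
            "total_acidity": acidity,
            "pzc": pzc,
        }
        records.append(
            StrainRecord(
                strain_id=sid,
                habitat=hab,
                profile=prof,
                markers=_draw_markers(hab, rng_marker),
                math_reading=(cfg.math_initial_od, cfg.math_initial_od * (1.0 - hydro[i])),
                zeta_potential=float(zeta[i]),
                titration=sample,
                eps_absorbances=(float(prot_abs), float(sugar_abs)),
                eps_n_cells=float(n_cells),
                true_traits=true_props,
            )
        )
        prop_rows.append({"habitat": hab, **true_props})

    truth = TruthBundle(
        config=cfg,
        properties=pd.DataFrame(prop_rows, index=pd.Index(ids, name="strain_id")),
        latent_genomic=pd.DataFrame(g, index=ids),
        latent_residual=pd.DataFrame(e, index=ids),
        similarity=sim,
        covariance=v,
        charge_scale=pd.Series(a_scale, index=ids, name="charge_scale"),
    )
    return SyntheticCohort(records, blank, protein_curve, sugar_curve, truth)


# ---------------------------------------------------------------------------
# On-disk cohort format (CSV + JSON, all plain text)

BLANK_ID = "__blank__"


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as strains/profiles/titrations/standards CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in cohort.records:
        m = r.markers
        rows.append(
            {
                "strain_id": r.strain_id,
                "habitat": r.habitat,
                "initial_od": r.math_reading[0],
                "aqueous_od": r.math_reading[1],
                "zeta_potential": r.zeta_potential,
                "protein_abs": r.eps_absorbances[0],
                "sugar_abs": r.eps_absorbances[1],
                "eps_n_cells": r.eps_n_cells,
                "n_bact": r.titration.n_bact,
                "arpA": int(m.arpA),
                "chuA": int(m.chuA),
                "yjaA": int(m.yjaA),
                "tspE4": int(m.tspE4),
                "group_c": m.group_c,
                "group_e": m.group_e,
            }
        )
    paths["strains"] = outdir / "strains.csv"
    pd.DataFrame(rows).to_csv(paths["strains"], index=False)

    prof_rows = []
    for r in cohort.records:
        for pos, inten in zip(r.profile.positions, r.profile.intensities):
            prof_rows.append({"strain_id": r.strain_id, "position_bp": pos, "intensity": inten})
    paths["profiles"] = outdir / "profiles.csv"
    pd.DataFrame(prof_rows).to_csv(paths["profiles"], index=False)

    tit_rows = []
    for r in cohort.records:
        t = r.titration
        for ph, ca, cb in zip(t.ph, t.c_acid, t.c_base):
            tit_rows.append({"strain_id": r.strain_id, "ph": ph, "c_acid": ca, "c_base": cb})
    b = cohort.blank
    for ph, ca, cb in zip(b.ph, b.c_acid, b.c_base):
        tit_rows.append({"strain_id": BLANK_ID, "ph": ph, "c_acid": ca, "c_base": cb})
    paths["titrations"] = outdir / "titrations.csv"
    pd.DataFrame(tit_rows).to_csv(paths["titrations"], index=False)

    std_rows = []
    for assay, curve in (("protein", cohort.protein_curve), ("sugar", cohort.sugar_curve)):
        for c, a in zip(curve.concentrations, curve.absorbances):
            std_rows.append({"assay": assay, "concentration": c, "absorbance": a})
    paths["standards"] = outdir / "standards.csv"
    pd.DataFrame(std_rows).to_csv(paths["standards"], index=False)

    if cohort.truth is not None:
        truth = cohort.truth
        payload = {
            "config": truth.config.as_dict(),
            "properties": truth.properties.reset_index().to_dict(orient="records"),
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload, indent=1, allow_nan=True))
    return paths


def read_profiles(indir: str | Path) -> list[BandProfile]:
    """Load the band profiles (long-format profiles.csv) of a cohort directory."""
    profiles = pd.read_csv(Path(indir) / "profiles.csv")
    out = []
    for sid, grp in profiles.groupby("strain_id", sort=False):
        grp = grp.sort_values("position_bp")
        out.append(BandProfile(str(sid), grp["position_bp"].to_numpy(),
                               grp["intensity"].to_numpy()))
    return out


def read_cohort(indir: str | Path, require_profiles: bool = True) -> SyntheticCohort:
    """Reconstruct a cohort (records + calibration objects) from disk.

    With ``require_profiles=False`` the fingerprint data may be absent; the
    records then carry ``profile=None`` (enough for the assay stage).
    """
    indir = Path(indir)
    strains = pd.read_csv(indir / "strains.csv")
    if require_profiles or (indir / "profiles.csv").exists():
        by_strain = {p.strain_id: p for p in read_profiles(indir)}
    else:
        by_strain = {}
    titrations = pd.read_csv(indir / "titrations.csv")
    standards = pd.read_csv(indir / "standards.csv")

    curves = {}
    for assay, grp in standards.groupby("assay"):
        curves[assay] = StandardCurve(grp["concentration"].to_numpy(), grp["absorbance"].to_numpy())

    blank_rows = titrations[titrations["strain_id"] == BLANK_ID]
    if blank_rows.empty:
        raise ValueError("titrations.csv contains no blank titration")
    blank = TitrationCurve(
        blank_rows["ph"].to_numpy(), blank_rows["c_acid"].to_numpy(),
        blank_rows["c_base"].to_numpy(), role="blank",
    )

    records = []
    for _, row in strains.iterrows():
        sid = row["strain_id"]
        prof = by_strain.get(sid)
        tit = titrations[titrations["strain_id"] == sid].sort_values("ph")
        if tit.empty or (require_profiles and prof is None):
            raise ValueError(f"strain {sid!r} missing profile or titration data")
        records.append(
            StrainRecord(
                strain_id=sid,
                habitat=row["habitat"],
                profile=prof,
                markers=MarkerProfile(
                    arpA=bool(row["arpA"]), chuA=bool(row["chuA"]),
                    yjaA=bool(row["yjaA"]), tspE4=bool(row["tspE4"]),
                    group_c=row["group_c"], group_e=row["group_e"],
                ),
                math_reading=(float(row["initial_od"]), float(row["aqueous_od"])),
                zeta_potential=float(row["zeta_potential"]),
                titration=TitrationCurve(
                    tit["ph"].to_numpy(), tit["c_acid"].to_numpy(), tit["c_base"].to_numpy(),
                    role="sample", n_bact=float(row["n_bact"]),
                ),
                eps_absorbances=(float(row["protein_abs"]), float(row["sugar_abs"])),
                eps_n_cells=float(row["eps_n_cells"]),
            )
        )
    return SyntheticCohort(records, blank, curves["protein"], curves["sugar"])
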