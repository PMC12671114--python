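"""Synthetic multi-cohort microbiome generator with planted ground truth.

The generator emulates the structure of a cross-cohort gut metagenomics
study in which the real patient tables cannot be shared: several cohorts of
tens of samples, a few hundred species collapsed into genera, compositional
abundances with dominant-genus enterotypes, cohort-specific centroid shifts
of controllable pairwise geometry, covariate (disease / medication / age /
sex) effects of controllable variance fractions, and structural zeros.

Model (per sample s, taxon i, all in log-abundance space):

    z_si = b_i + boost_{e(s),i} + shift_{c(s),i} + sum_v x_sv * beta_vi + eps_si

with b a fixed baseline profile, e(s) the sample's enterotype, c(s) its
cohort, x_sv covariate values and eps ~ N(0, dispersion^2).  Abundances are
exp(z), hit by structural zeros (never a sample's top-3 taxa), and re-closed
to 100 percent.

Shift vectors are constructed zero-sum (orthogonal to the all-ones log
direction), which the closure annihilates, so the pairwise angles planted
between cohort shifts survive the compositional closure and the downstream
square-root/autoscale transform approximately intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AbundanceTable, GutcompassError, SampleMetadata

__all__ = [
    "CovariateEffect",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_cohorts",
    "calibrate_variance_fraction",
    "calibrate_spec",
    "shift_vectors_from_angles",
    "default_study_spec",
    "angle_benchmark_spec",
    "enterotype_benchmark_spec",
    "variance_benchmark_spec",
]


@dataclass
class CovariateEffect:
    """A planted covariate -> taxon effect.

    ``kind`` decides how the covariate value is built per sample:
    'flag' (an existing 0/1 metadata column), 'age' (z-scored age),
    'sex' (0/1), 'disease' (0/1).  ``target_fraction`` is the share of
    total log-space variance the effect should explain after calibration
    (None = use the vector as given).
    """

    effect: np.ndarray
    kind: str = "flag"
    target_fraction: float | None = None


@dataclass
class SyntheticSpec:
    cohorts: dict[str, int]
    n_taxa: int = 200
    n_genera: int = 40
    n_enterotypes: int = 3
    enterotype_dominance: float = 4.0     # log-units boost to driver-genus taxa
    cohort_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    medication_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    disease_cohorts: tuple[str, ...] = ()
    age_mean: dict[str, float] | float = 60.0
    age_sd: float = 10.0
    sex_rate: float = 0.55
    base_sd: float = 1.0                  # spread of the baseline log profile
    base_log_profile: np.ndarray | None = None  # fixed baseline (else drawn)
    dispersion: float = 1.0               # log-normal noise scale
    zero_rate: float = 0.1                # structural-zero probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.zero_rate < 1):
            raise GutcompassError("zero_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise GutcompassError("dispersion must be positive")
        for label, vec in self.cohort_shifts.items():
            if label not in self.cohorts:
                raise GutcompassError(f"shift for unknown cohort '{label}'")
            if len(vec) != self.n_taxa:
                raise GutcompassError(
                    f"shift vector for '{label}' has wrong length"
                )


@dataclass
class GroundTruth:
    """Exactly what was planted, for recovery tests downstream."""

    cohort_angles: dict[tuple[str, str], float]
    enterotype_labels: pd.Series
    variance_fractions: dict[str, float]
    associations: list[tuple[str, str, int]]  # (covariate, taxon, sign)

    def to_json(self, path) -> None:
        payload = {
            "cohort_angles": {f"{a}|{b}": v
                              for (a, b), v in self.cohort_angles.items()},
            "enterotype_labels": {str(k): int(v)
                                  for k, v in self.enterotype_labels.items()},
            "variance_fractions": self.variance_fractions,
            "associations": [list(t) for t in self.associations],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _taxonomy(n_taxa: int, n_genera: int) -> tuple[list[str], np.ndarray]:
    """Clade strings for species round-robin assigned to genera."""
    genus_of = np.arange(n_taxa) % n_genera
    labels = []
    per_genus_count: dict[int, int] = {}
    for i in range(n_taxa):
        g = genus_of[i]
        per_genus_count[g] = per_genus_count.get(g, 0) + 1
        phylum = g % 5 + 1
        labels.append(
            f"k__Bacteria|p__P{phylum:02d}|c__C{phylum:02d}|o__O{phylum:02d}"
            f"|f__F{g + 1:03d}|g__G{g + 1:03d}|s__G{g + 1:03d}_sp{per_genus_count[g]}"
        )
    return labels, genus_of


def shift_vectors_from_angles(labels: list[str], angles_deg: dict | np.ndarray,
                              magnitudes, n_taxa: int,
                              rng: np.random.Generator,
                              orthogonal_to=None) -> dict[str, np.ndarray]:
    """Build zero-sum cohort shift vectors with prescribed pairwise angles.

    The target Gram matrix G_ab = m_a m_b cos(theta_ab) must be positive
    semidefinite (realizable geometry); it is factored and embedded on a
    random orthonormal basis orthogonal to the all-ones direction and to any
    additional directions in ``orthogonal_to`` (passing the expected
    composition keeps the compositional closure from leaking a planted
    shift into the shared all-taxon direction).
    """
    k = len(labels)
    mags = np.broadcast_to(np.asarray(magnitudes, dtype=float), (k,))
    theta = np.zeros((k, k))
    if isinstance(angles_deg, dict):
        for (a, b), ang in angles_deg.items():
            ia, ib = labels.index(a), labels.index(b)
            theta[ia, ib] = theta[ib, ia] = ang
    else:
        theta = np.asarray(angles_deg, dtype=float)
    gram = np.outer(mags, mags) * np.cos(np.radians(theta))
    np.fill_diagonal(gram, mags ** 2)
    eigval, eigvec = np.linalg.eigh(gram)
    if eigval.min() < -1e-8 * max(1.0, abs(eigval).max()):
        raise GutcompassError(
            f"requested pairwise angles are not realizable "
            f"(Gram matrix has eigenvalue {eigval.min():.3g} < 0)"
        )
    tol = 1e-10 * max(1.0, eigval.max())
    keep = eigval > tol
    v = eigvec[:, keep] * np.sqrt(eigval[keep])   # k x r factor of the Gram
    d = int(keep.sum())
    if d == 2:
        # equal-row-norm embedding: spreads the planted signal evenly over
        # taxa, so no single taxon carries a disproportionate share (keeps
        # the per-feature autoscaling from warping the planted plane)
        phi = 2.0 * np.pi * (np.arange(n_taxa) + rng.random()) / n_taxa
        raw = np.column_stack([np.cos(phi), np.sin(phi)])
        raw = raw[rng.permutation(n_taxa)]
        rot = np.linalg.qr(rng.standard_normal((2, 2)))[0]
        raw = raw @ rot
    else:
        raw = rng.standard_normal((n_taxa, d))
    guard = [np.ones(n_taxa)]
    if orthogonal_to is not None:
        extra = np.atleast_2d(np.asarray(orthogonal_to, dtype=float))
        guard.extend(list(extra))
    for g in guard:
        g = g / np.linalg.norm(g)
        raw -= np.outer(g, g @ raw)
    q, _ = np.linalg.qr(raw)
    shifts = {lab: v[i] @ q.T for i, lab in enumerate(labels)}
    return shifts


def _covariate_values(name: str, eff: CovariateEffect,
                      meta: pd.DataFrame) -> np.ndarray:
    if eff.kind == "age":
        age = meta["age"].to_numpy(dtype=float)
        sd = age.std(ddof=1)
        return (age - age.mean()) / (sd if sd > 0 else 1.0)
    if eff.kind == "sex":
        return meta["sex"].to_numpy(dtype=float)
    if eff.kind == "disease":
        return meta["disease"].to_numpy(dtype=float)
    if eff.kind == "flag":
        col = name if name in meta.columns else f"med_{name}"
        if col not in meta.columns:
            raise GutcompassError(f"no metadata column for covariate '{name}'")
        return meta[col].to_numpy(dtype=float)
    raise GutcompassError(f"unknown covariate kind '{eff.kind}'")


def simulate_cohorts(spec: SyntheticSpec, seed: int | None = None
                     ) -> tuple[AbundanceTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic study from the spec.  Same spec + seed => same data."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels, genus_of = _taxonomy(spec.n_taxa, spec.n_genera)
    cohort_names = list(spec.cohorts)
    n_total = sum(spec.cohorts.values())

    # ----- metadata ---------------------------------------------------------
    rows = []
    for cohort in cohort_names:
        n = spec.cohorts[cohort]
        mean_age = (spec.age_mean[cohort]
                    if isinstance(spec.age_mean, dict) else spec.age_mean)
        ages = np.clip(rng.normal(mean_age, spec.age_sd, size=n), 18.0, None)
        sexes = rng.binomial(1, spec.sex_rate, size=n)
        for i in range(n):
            rows.append({
                "sample_id": f"{cohort}_{i + 1:03d}",
                "cohort": cohort,
                "age": round(float(ages[i]), 1),
                "sex": int(sexes[i]),
                "disease": int(cohort in spec.disease_cohorts),
            })
    meta_df = pd.DataFrame(rows)
    med_cols = []
    for med, rates in spec.medication_rates.items():
        col = f"med_{med}"
        med_cols.append(col)
        vals = np.zeros(n_total, dtype=int)
        for cohort in cohort_names:
            mask = (meta_df["cohort"] == cohort).to_numpy()
            rate = rates.get(cohort, 0.0) if isinstance(rates, dict) else rates
            vals[mask] = rng.binomial(1, rate, size=mask.sum())
        meta_df[col] = vals

    # ----- log-abundance model ---------------------------------------------
    if spec.base_log_profile is not None:
        base = np.asarray(spec.base_log_profile, dtype=float)
        rng.normal(0.0, spec.base_sd, size=spec.n_taxa)  # keep stream aligned
    else:
        base = rng.normal(0.0, spec.base_sd, size=spec.n_taxa)
    driver_genera = rng.permutation(spec.n_genera)[: spec.n_enterotypes]
    boosts = np.zeros((spec.n_enterotypes, spec.n_taxa))
    for e, g in enumerate(driver_genera):
        boosts[e, genus_of == g] = spec.enterotype_dominance
    enterotype = rng.integers(0, spec.n_enterotypes, size=n_total)

    z = np.tile(base, (n_total, 1)) + boosts[enterotype]
    cohort_arr = meta_df["cohort"].to_numpy()
    for cohort, shift in spec.cohort_shifts.items():
        z[cohort_arr == cohort] += np.asarray(shift, dtype=float)
    # derive any_medication before effects so its planted effect is consistent
    if med_cols:
        meta_df["any_medication"] = meta_df[med_cols].max(axis=1).astype(int)
    else:
        meta_df["any_medication"] = 0
    for name, eff in spec.covariate_effects.items():
        x = (_covariate_values(name, eff, meta_df)
             if eff.kind != "flag" or name != "any_medication"
             else meta_df["any_medication"].to_numpy(dtype=float))
        z += np.outer(x, np.asarray(eff.effect, dtype=float))
    z += rng.normal(0.0, spec.dispersion, size=z.shape)

    # ----- compositional closure with structural zeros ----------------------
    abund = np.exp(z - z.max(axis=1, keepdims=True))
    if spec.zero_rate > 0:
        mask = rng.random(abund.shape) < spec.zero_rate
        top3 = np.argsort(abund, axis=1)[:, -3:]
        rows_idx = np.arange(n_total)[:, None]
        mask[rows_idx, top3] = False
        abund = np.where(mask, 0.0, abund)
    abund = 100.0 * abund / abund.sum(axis=1, keepdims=True)

    table = AbundanceTable(
        data=pd.DataFrame(abund, index=meta_df["sample_id"].to_numpy(),
                          columns=labels),
        rank="species",
    )
    meta = SampleMetadata(data=meta_df, medication_columns=med_cols)

    # ----- ground truth ------------------------------------------------------
    angles: dict[tuple[str, str], float] = {}
    shifted = [c for c in cohort_names if c in spec.cohort_shifts
               and np.linalg.norm(spec.cohort_shifts[c]) > 0]
    for i, a in enumerate(shifted):
        for b in shifted[i + 1:]:
            u, v = spec.cohort_shifts[a], spec.cohort_shifts[b]
            cosang = np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1
            )
            angles[(a, b)] = float(np.degrees(np.arccos(cosang)))
    fractions = {name: eff.target_fraction
                 for name, eff in spec.covariate_effects.items()
                 if eff.target_fraction is not None}
    associations = []
    for name, eff in spec.covariate_effects.items():
        vec = np.asarray(eff.effect, dtype=float)
        if vec.any():
            thresh = 0.5 * np.abs(vec).max()
            for i in np.flatnonzero(np.abs(vec) >= thresh):
                associations.append((name, labels[i], int(np.sign(vec[i]))))
    truth = GroundTruth(
        cohort_angles=angles,
        enterotype_labels=pd.Series(enterotype + 1,
                                    index=meta_df["sample_id"].to_numpy(),
                                    name="enterotype"),
        variance_fractions=fractions,
        associations=associations,
    )
    return table, meta, truth


def _realized_fraction(spec: SyntheticSpec, name: str, seed: int) -> float:
    """Adjusted single-covariate explained-variance share in clr space."""
    from .transforms import clr_transform
    from .variance import rda

    table, meta, _ = simulate_cohorts(spec, seed=seed)
    eff = spec.covariate_effects[name]
    x = _covariate_values(name, eff, meta.data.reset_index(drop=True))
    clr = clr_transform(table)
    res = rda(clr, pd.DataFrame({name: x}))
    return max(res.adj_r2, 0.0)


def calibrate_variance_fraction(effect_vector, target_fraction: float,
                                spec: SyntheticSpec, name: str = "_cal_",
                                kind: str = "flag",
                                n_sim: int = 3) -> np.ndarray:
    """Scale an effect vector so the covariate explains ``target_fraction``.

    The scale is established by simulation at the spec's own sample sizes:
    an analytic first guess from the residual log-space variance of a
    simulation without the effect, then one multiplicative correction from
    the realized adjusted R^2 with the effect applied (averaged over
    ``n_sim`` replicates).  This absorbs closure, pseudocount and
    structural-zero attenuation that a purely analytic scale would miss.
    """
    beta = np.asarray(effect_vector, dtype=float).copy()
    if target_fraction == 0:
        return np.zeros_like(beta)
    if not 0 < target_fraction < 1:
        raise GutcompassError("target_fraction must be in (0, 1)")
    if not beta.any():
        raise GutcompassError(
            "zero effect vector cannot reach a positive target "
            "(attainable bound: 0)"
        )
    beta = beta - beta.mean()            # closure removes the mean anyway
    if not beta.any():
        raise GutcompassError(
            "constant effect vector is removed by closure "
            "(attainable bound: 0)"
        )
    cal_seed = (spec.seed * 7919 + 104729) % (2 ** 31)
    base_spec = replace(
        spec,
        covariate_effects={
            **{k: v for k, v in spec.covariate_effects.items() if k != name},
            name: CovariateEffect(effect=np.zeros_like(beta), kind=kind),
        },
    )
    table, meta, _ = simulate_cohorts(base_spec, seed=cal_seed)
    x = _covariate_values(name, CovariateEffect(effect=beta, kind=kind),
                          meta.data.reset_index(drop=True))
    var_x = float(np.var(x, ddof=1))
    if var_x == 0:
        raise GutcompassError(f"covariate '{name}' has zero variance")
    from .transforms import clr_transform
    clr = clr_transform(table).values
    v_rest = float((clr - clr.mean(axis=0)).var(axis=0, ddof=1).sum())
    f = target_fraction
    s0 = np.sqrt(f / (1 - f) * v_rest / (var_x * float(beta @ beta)))
    scale = s0
    for it in range(4):
        trial = replace(
            base_spec,
            covariate_effects={
                **{k: v for k, v in base_spec.covariate_effects.items()
                   if k != name},
                name: CovariateEffect(effect=scale * beta, kind=kind),
            },
        )
        realized = np.mean([
            _realized_fraction(trial, name,
                               seed=(cal_seed + 1 + 10 * it + j) % (2 ** 31))
            for j in range(n_sim)
        ])
        if realized <= 0:
            raise GutcompassError(
                f"target fraction {target_fraction} unreachable at this "
                f"noise scale (realized {realized:.4f} at scale {scale:.3g})"
            )
        if abs(realized - f) < 0.05 * f:
            break
        correction = np.sqrt((f / (1 - f)) / (realized / (1 - realized)))
        scale *= float(np.clip(correction, 1 / 3, 3.0))
    return scale * beta


def calibrate_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Return a spec whose targeted covariate effects are calibrated."""
    effects = {}
    for name, eff in spec.covariate_effects.items():
        if eff.target_fraction is None:
            effects[name] = eff
        else:
            scaled = calibrate_variance_fraction(
                eff.effect, eff.target_fraction, spec, name=name, kind=eff.kind
            )
            effects[name] = CovariateEffect(effect=scaled, kind=eff.kind,
                                            target_fraction=eff.target_fraction)
    return replace(spec, covariate_effects=effects)


# ---------------------------------------------------------------------------
# Scenario builders: the study conditions, stated once
# ---------------------------------------------------------------------------

def _sparse_effect(rng: np.random.Generator, n_taxa: int,
                   n_hits: int = 10) -> np.ndarray:
    """A zero-mean effect vector concentrated on a few taxa."""
    beta = np.zeros(n_taxa)
    idx = rng.choice(n_taxa, size=n_hits, replace=False)
    beta[idx] = rng.choice([-1.0, 1.0], size=n_hits)
    return beta - beta.mean()


def default_study_spec(seed: int = 0) -> SyntheticSpec:
    """Desk-scale emulation of a six-cohort-style study: 5 cohorts x 60
    samples, 200 species in 40 genera, 3 enterotypes, cohort shifts of
    moderate magnitude, and disease/medication/age/sex effects targeted at
    the few-percent variance fractions such studies report."""
    rng = np.random.default_rng(seed)
    cohorts = ["CLL", "preHSCT_AML", "other_preHSCT", "cardiac", "healthy"]
    n_taxa = 200
    shifts = shift_vectors_from_angles(
        cohorts,
        {(a, b): ang for (a, b), ang in {
            ("CLL", "preHSCT_AML"): 141.0, ("CLL", "other_preHSCT"): 112.0,
            ("CLL", "cardiac"): 42.0, ("CLL", "healthy"): 99.0,
            ("preHSCT_AML", "other_preHSCT"): 45.0,
            ("preHSCT_AML", "cardiac"): 150.0,
            ("preHSCT_AML", "healthy"): 110.0,
            ("other_preHSCT", "cardiac"): 120.0,
            ("other_preHSCT", "healthy"): 100.0,
            ("cardiac", "healthy"): 80.0,
        }.items()},
        magnitudes=2.0, n_taxa=n_taxa, rng=rng,
    )
    med_rates = {
        "J01": {"CLL": 0.19, "preHSCT_AML": 0.9, "other_preHSCT": 0.6,
                "cardiac": 0.06, "healthy": 0.0},
        "B01": {"CLL": 0.15, "preHSCT_AML": 0.2, "other_preHSCT": 0.2,
                "cardiac": 0.65, "healthy": 0.0},
        "C10": {"CLL": 0.08, "preHSCT_AML": 0.05, "other_preHSCT": 0.05,
                "cardiac": 0.58, "healthy": 0.0},
        "A02": {"CLL": 0.05, "preHSCT_AML": 0.3, "other_preHSCT": 0.3,
                "cardiac": 0.26, "healthy": 0.0},
        "H02": {"CLL": 0.06, "preHSCT_AML": 0.4, "other_preHSCT": 0.3,
                "cardiac": 0.0, "healthy": 0.0},
        "N05": {"CLL": 0.11, "preHSCT_AML": 0.2, "other_preHSCT": 0.2,
                "cardiac": 0.47, "healthy": 0.0},
    }
    effects = {
        "disease": CovariateEffect(_sparse_effect(rng, n_taxa, 20),
                                   kind="disease", target_fraction=0.030),
        "any_medication": CovariateEffect(_sparse_effect(rng, n_taxa, 15),
                                          kind="flag", target_fraction=0.013),
        "age": CovariateEffect(_sparse_effect(rng, n_taxa, 20), kind="age",
                               target_fraction=0.009),
        "sex": CovariateEffect(_sparse_effect(rng, n_taxa, 20), kind="sex",
                               target_fraction=0.008),
        "J01": CovariateEffect(_sparse_effect(rng, n_taxa, 12), kind="flag",
                               target_fraction=0.008),
        "H02": CovariateEffect(_sparse_effect(rng, n_taxa, 12), kind="flag",
                               target_fraction=0.015),
    }
    return SyntheticSpec(
        cohorts={c: 60 for c in cohorts},
        n_taxa=n_taxa, n_genera=40, n_enterotypes=3,
        enterotype_dominance=4.0,
        cohort_shifts=shifts,
        covariate_effects=effects,
        medication_rates=med_rates,
        disease_cohorts=("CLL", "preHSCT_AML", "other_preHSCT", "cardiac"),
        age_mean={"CLL": 68.0, "preHSCT_AML": 60.0, "other_preHSCT": 59.0,
                  "cardiac": 65.0, "healthy": 55.0},
        seed=seed,
    )


#: shift-vector scale for the angle benchmark, in units of the log-noise SD:
#: calibrated so planted between-cohort separation dominates both the
#: within-cohort sampling noise and the transform's nonlinear distortion
ANGLE_SIGNAL_SCALE = 5.0


def angle_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """Four cohorts of 60 samples, 200 taxa, planted in a 2-plane.

    The centroid-angle estimator measures vectors from the grand mean of
    the data, so the planted shifts sum to zero across the (equal-sized)
    cohorts: directions 0/45/225/90 degrees, whose pairwise angle set is
    exactly {45, 90, 135, 180}, keeping the planted frame identical to the
    estimator's grand-mean frame.  Magnitudes within the sum-zero family
    (m_ref = m_ortho = (m_anti_near - m_near)/sqrt 2) are chosen to keep
    the reference direction oblique to both between-cohort principal axes
    (so the reference-vs-rest screen retains the whole signal plane) and
    the between-cohort covariance as isotropic as the angle set permits
    (limiting the warp that per-feature autoscaling applies to the plane).
    Structural zeros are disabled here: the benchmark measures geometry in
    square-root space, where zero-inflation noise would swamp the planted
    plane at this dispersion.
    """
    rng = np.random.default_rng(seed)
    labels = ["ref", "near", "anti_near", "ortho"]
    directions = {"ref": 0.0, "near": 45.0, "anti_near": 225.0, "ortho": 90.0}
    rel_mag = {"ref": 2.0 / np.sqrt(2), "near": 0.6, "anti_near": 2.6,
               "ortho": 2.0 / np.sqrt(2)}
    theta = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            diff = abs(directions[a] - directions[b]) % 360.0
            theta[i, j] = min(diff, 360.0 - diff)
    dispersion = 0.35
    base_sd = 0.5
    mags = [ANGLE_SIGNAL_SCALE * dispersion * rel_mag[c] for c in labels]
    base = rng.normal(0.0, base_sd, size=200)
    p0 = np.exp(base) / np.exp(base).sum()
    shifts = shift_vectors_from_angles(
        labels, theta, magnitudes=mags, n_taxa=200, rng=rng,
        orthogonal_to=p0,
    )
    return SyntheticSpec(
        cohorts={c: 60 for c in labels},
        n_taxa=200, n_genera=40, n_enterotypes=1, enterotype_dominance=0.0,
        cohort_shifts=shifts, dispersion=dispersion, base_sd=base_sd,
        base_log_profile=base, zero_rate=0.0, seed=seed,
    )


def enterotype_benchmark_spec(seed: int = 0, n_enterotypes: int = 3) -> SyntheticSpec:
    """Three planted enterotypes with disjoint driver genera, dominance well
    above the log-noise scale; cohort structure deliberately absent."""
    return SyntheticSpec(
        cohorts={"A": 60, "B": 60, "C": 60},
        n_taxa=200, n_genera=40,
        n_enterotypes=n_enterotypes, enterotype_dominance=4.0,
        seed=seed,
    )


def variance_benchmark_spec(target_fraction: float = 0.10,
                            seed: int = 0, n_hits: int = 200,
                            rate: float = 0.5) -> SyntheticSpec:
    """One cohort-free population with a single binary covariate planted at
    ``target_fraction`` of total variance.

    The effect is dense by default (every taxon nudged a little) so the
    per-taxon log shift stays in the regime where the clr response is
    linear; concentrating the same variance on few taxa would need shifts
    so large they saturate against the zero/pseudocount floor.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(
        cohorts={"A": 60, "B": 60},
        n_taxa=200, n_genera=40, n_enterotypes=1, enterotype_dominance=0.0,
        medication_rates={"X": rate},
        covariate_effects={
            "med_X": CovariateEffect(_sparse_effect(rng, 200, n_hits),
                                     kind="flag",
                                     target_fraction=target_fraction),
        },
        seed=seed,
    )
    return spec


def association_benchmark_spec(seed: int = 0, n_taxa: int = 500,
                               n_meds: int = 10, true_frac: float = 0.05,
                               effect_size: float = 2.5,
                               n_per_group: int = 75) -> SyntheticSpec:
    """A drug-taxon association study: ``n_taxa * n_meds`` candidate tests
    with ``true_frac`` of the pairs carrying a real effect of
    ``effect_size`` log-units (about one clr-space noise SD once the
    zero/pseudocount spikes are counted in)."""
    rng = np.random.default_rng(seed)
    meds = [f"M{i:02d}" for i in range(n_meds)]
    n_true_per_med = max(1, int(round(true_frac * n_taxa)))
    effects = {}
    for med in meds:
        beta = np.zeros(n_taxa)
        idx = rng.choice(n_taxa, size=n_true_per_med, replace=False)
        beta[idx] = effect_size * rng.choice([-1.0, 1.0], size=n_true_per_med)
        effects[f"med_{med}"] = CovariateEffect(beta, kind="flag")
    return SyntheticSpec(
        cohorts={"A": n_per_group, "B": n_per_group},
        n_taxa=n_taxa, n_genera=50, n_enterotypes=1, enterotype_dominance=0.0,
        medication_rates={m: 0.5 for m in meds},
        covariate_effects=effects,
        seed=seed,
    )


def stepwise_benchmark_spec(seed: int = 0, n_planted: int = 2, n_null: int = 8,
                            planted_fraction: float = 0.05) -> SyntheticSpec:
    """Ten candidate medications, ``n_planted`` with dense effects at
    ``planted_fraction`` of total variance each, the rest pure null."""
    rng = np.random.default_rng(seed)
    meds = [f"M{i:02d}" for i in range(n_planted + n_null)]
    effects = {}
    for i in range(n_planted):
        effects[f"med_{meds[i]}"] = CovariateEffect(
            _sparse_effect(rng, 200, 200), kind="flag",
            target_fraction=planted_fraction,
        )
    return SyntheticSpec(
        cohorts={"A": 60, "B": 60},
        n_taxa=200, n_genera=40, n_enterotypes=1, enterotype_dominance=0.0,
        medication_rates={m: 0.5 for m in meds},
        covariate_effects=effects,
        seed=seed,
    )
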