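"""Synthetic paired-tissue and survival-cohort generator with known truth.

Emulates the data layout of a two-arm miRNA biomarker study: a small set of
tumour / adjacent-normal tissue pairs profiled genome-wide (log2
intensities, planted fold-changes), and patient cohorts with qRT-PCR
expression of candidate features, proportional-hazards progression-free
survival driven by a planted linear predictor, independent censoring, and
RECIST best-response categories stochastically linked to the same linear
predictor through an ordinal logit.

Every generated object is accompanied by a :class:`GroundTruth` record;
pipeline stages never read it — it exists purely so tests can score
recovery.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio
from .io import ClinicalCohort, ExpressionMatrix, MirsigError


class SimulationError(MirsigError):
    pass


@dataclasses.dataclass
class SimulationDesign:
    """Study-shaped simulation parameters.

    The defaults mirror the emulated study: 21 tissue pairs, a 67-patient
    training cohort with 40- and 44-patient validation cohorts, ~15% of
    features differentially expressed with a 1.5 log2-unit shift, and two
    prognostic features whose default per-log2-unit hazard coefficients
    (-0.26, +0.09) echo the published signature.  ``scaled_effects`` returns
    a copy with the planted coefficients multiplied up, for
    power/recovery experiments at detectable effect size.
    """

    n_features: int = 200
    n_pairs: int = 21
    n_patients: int = 67
    n_internal: int = 40
    n_external: int = 44
    de_fraction: float = 0.15
    log2_fold_effect: float = 1.5
    feature_sd: float = 0.8
    pair_sd: float = 0.5
    planted_beta: dict | None = None
    weibull_shape: float = 1.0
    baseline_median_months: float = 10.0
    censor_rate_target: float = 0.25
    follow_up_months: float = 60.0
    response_link_slope: float = 1.0
    response_mix: tuple = (0.04, 0.30, 0.46, 0.20)   # CR, PR, SD, PD marginal mix

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise SimulationError("need at least 3 tissue pairs")
        if self.n_patients < 10:
            raise SimulationError("need at least 10 patients in a cohort")
        if int(self.de_fraction * self.n_features) < 1:
            raise SimulationError("de_fraction * n_features must be >= 1")
        if not 0 <= self.censor_rate_target < 1:
            raise SimulationError("censor_rate_target must lie in [0,1)")
        if self.feature_sd <= 0 or self.weibull_shape <= 0 or self.baseline_median_months <= 0:
            raise SimulationError("scale parameters must be positive")
        if abs(sum(self.response_mix) - 1.0) > 1e-9:
            raise SimulationError("response_mix must sum to 1")
        if self.planted_beta is None:
            ids = self.feature_ids
            self.planted_beta = {ids[0]: -0.26, ids[1]: 0.09}
        unknown = set(self.planted_beta) - set(self.feature_ids)
        if unknown:
            raise SimulationError(f"planted_beta names unknown features: {sorted(unknown)}")
        if all(b == 0 for b in self.planted_beta.values()) and self.response_link_slope != 0:
            import warnings

            warnings.warn("planted_beta is all zero: response categories carry no signal",
                          stacklevel=2)

    @property
    def feature_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_features)]

    @property
    def n_de(self) -> int:
        return int(self.de_fraction * self.n_features)

    @property
    def de_feature_ids(self) -> list[str]:
        return self.feature_ids[: self.n_de]

    def scaled_effects(self, factor: float) -> "SimulationDesign":
        new = dataclasses.replace(self)
        new.planted_beta = {k: v * factor for k, v in self.planted_beta.items()}
        return new


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted; written next to fixtures, never read by
    pipeline stages."""

    de_up: list
    de_down: list
    planted_beta: dict
    linear_predictor: dict     # sample id -> true lp (cohort arms only)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        mio.write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls(**mio.read_json(path))


def simulate_paired_tissues(design: SimulationDesign, seed):
    """Paired tumour/normal log2 expression with planted fold-changes.

    The first half of the DE block is shifted up in tumour, the second half
    down, by ``log2_fold_effect``; a per-pair random effect induces the
    within-pair correlation a paired test exploits.

    Returns (ExpressionMatrix, pairing map, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    ids = design.feature_ids
    n_de = design.n_de
    de_up = ids[: n_de // 2 + n_de % 2]
    de_down = ids[n_de // 2 + n_de % 2: n_de]
    shift = np.zeros(design.n_features)
    shift[: len(de_up)] = design.log2_fold_effect
    shift[len(de_up): n_de] = -design.log2_fold_effect

    means = rng.uniform(4.0, 12.0, design.n_features)
    pair_eff = rng.normal(0.0, design.pair_sd, (design.n_features, design.n_pairs))
    noise_t = rng.normal(0.0, design.feature_sd, (design.n_features, design.n_pairs))
    noise_n = rng.normal(0.0, design.feature_sd, (design.n_features, design.n_pairs))
    tumour = means[:, None] + shift[:, None] + pair_eff + noise_t
    normal = means[:, None] + pair_eff + noise_n

    t_ids = [f"T{i + 1:02d}" for i in range(design.n_pairs)]
    n_ids = [f"N{i + 1:02d}" for i in range(design.n_pairs)]
    frame = pd.DataFrame(np.hstack([tumour, normal]), index=ids, columns=t_ids + n_ids)
    pairing = {f"P{i + 1:02d}": (t_ids[i], n_ids[i]) for i in range(design.n_pairs)}
    truth = GroundTruth(de_up=de_up, de_down=de_down,
                        planted_beta=dict(design.planted_beta), linear_predictor={})
    return ExpressionMatrix(frame, scale="log"), pairing, truth


def _censoring_rate(mu, surv_fn, tau, grid):
    """Expected censoring fraction with C = min(Exp(mu), tau)."""
    S = surv_fn(grid)                       # n_patients x n_grid
    dens = mu * np.exp(-mu * grid)
    integral = np.trapezoid(dens[None, :] * S, grid, axis=1)
    admin = np.exp(-mu * tau) * surv_fn(np.array([tau]))[:, 0]
    return float(np.mean(integral + admin))


def _solve_censor_rate(target, surv_fn, tau):
    """Bisection for the exponential censoring rate hitting ``target``."""
    grid = np.linspace(1e-9, tau, 400)
    lo, hi = 1e-8, 5.0
    if _censoring_rate(lo, surv_fn, tau, grid) >= target:
        return lo   # administrative censoring alone already reaches target
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _censoring_rate(mid, surv_fn, tau, grid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(design: SimulationDesign, seed, n_patients: int | None = None,
                    cohort: str = "training", feature_ids=None, feature_means=None):
    """A patient cohort: qRT-PCR-scale expression, PFS, response categories.

    Expression is generated directly on the log2(10000 * 2^-dCt) scale.
    Event times follow a Weibull proportional-hazards model
    h(t) = h0(t) exp(beta' x_centered); censoring is an independent
    exponential/administrative mix calibrated to ``censor_rate_target``;
    best response is an ordinal logit on the true linear predictor (higher
    risk => more progressive disease).

    ``feature_means`` fixes the per-feature population means; cohorts of one
    study must share them so that risk scores (and the training cutoff) are
    comparable across cohorts, as they are for a single qRT-PCR assay.

    Returns (ExpressionMatrix, ClinicalCohort, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    n = n_patients if n_patients is not None else design.n_patients
    if n < 10:
        raise SimulationError("need at least 10 patients in a cohort")
    ids = list(feature_ids) if feature_ids is not None else design.de_feature_ids
    p = len(ids)
    sample_ids = [f"{cohort[:2].upper()}{i + 1:03d}" for i in range(n)]

    if feature_means is None:
        means = rng.uniform(2.0, 10.0, p)
    else:
        means = np.asarray(feature_means, dtype=float)
        if means.size != p:
            raise SimulationError("feature_means length mismatch")
    X = means[None, :] + rng.normal(0.0, design.feature_sd, (n, p))
    beta = np.array([design.planted_beta.get(f, 0.0) for f in ids])
    lp = (X - means[None, :]) @ beta

    k = design.weibull_shape
    lam0 = design.baseline_median_months / np.log(2) ** (1.0 / k)
    T = lam0 * (rng.exponential(1.0, n) / np.exp(lp)) ** (1.0 / k)

    if design.censor_rate_target <= 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        def surv_fn(ts):
            return np.exp(-np.outer(np.exp(lp), (ts / lam0) ** k))

        mu = _solve_censor_rate(design.censor_rate_target, surv_fn, design.follow_up_months)
        C = np.minimum(rng.exponential(1.0 / mu, n), design.follow_up_months)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    time = np.maximum(time, 1e-3)   # guard: positive times

    # ordinal logit response with cutpoints at the marginal category mix
    cum = np.cumsum(design.response_mix)[:-1]
    cuts = logit(cum)
    lp_c = lp - lp.mean()
    pcum = expit(cuts[None, :] - design.response_link_slope * lp_c[:, None])
    u = rng.uniform(size=n)
    cat_idx = (u[:, None] > pcum).sum(axis=1)
    response = np.array(["CR", "PR", "SD", "PD"])[cat_idx]

    chemo = rng.choice(["FOLFOX", "FOLFIRI"], size=n, p=[0.75, 0.25])
    expr = ExpressionMatrix(pd.DataFrame(X.T, index=ids, columns=sample_ids), scale="log")
    clin = ClinicalCohort(
        pd.DataFrame(
            {"pfs_months": np.round(time, 3), "event": event,
             "response": response, "chemotherapy": chemo},
            index=sample_ids,
        ),
        name=cohort,
    )
    truth = GroundTruth(de_up=[], de_down=[], planted_beta=dict(design.planted_beta),
                        linear_predictor={s: float(v) for s, v in zip(sample_ids, lp)})
    return expr, clin, truth


@dataclasses.dataclass
class StudyData:
    """One full synthetic study: the paired-tissue arm plus three cohorts."""

    design: SimulationDesign
    paired_expr: ExpressionMatrix
    pairing: dict
    truth_paired: GroundTruth
    cohorts: dict   # name -> (ExpressionMatrix, ClinicalCohort, GroundTruth)


def simulate_study(design: SimulationDesign, seed) -> StudyData:
    """Generate the paired arm and training/internal/external cohorts.

    Cohort expression covers the DE block only (the candidate features a
    qRT-PCR panel would measure), so the planted prognostic pair is present
    in every arm.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_pair, s_means, s_tr, s_in, s_ex = ss.spawn(5)
    paired_expr, pairing, truth_paired = simulate_paired_tissues(design, s_pair)
    # one shared set of assay-level feature means across cohorts
    means = np.random.default_rng(s_means).uniform(2.0, 10.0, len(design.de_feature_ids))
    cohorts = {
        "training": simulate_cohort(design, s_tr, design.n_patients, "training",
                                    feature_means=means),
        "internal": simulate_cohort(design, s_in, design.n_internal, "internal",
                                    feature_means=means),
        "external": simulate_cohort(design, s_ex, design.n_external, "external",
                                    feature_means=means),
    }
    return StudyData(design=design, paired_expr=paired_expr, pairing=pairing,
                     truth_paired=truth_paired, cohorts=cohorts)


def to_linear_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the log2(10000 x) normalization, giving raw 2^-dCt values."""
    out = expr.data.copy()
    out.loc[:, :] = 2.0 ** expr.data.to_numpy(float) / 10000.0
    return ExpressionMatrix(out, scale="linear")


def write_fixture_set(out_dir, design: SimulationDesign, seed, force: bool = False) -> dict:
    """Write a complete re-readable fixture set; returns a file manifest.

    Cohort expression is written on the raw relative (2^-dCt) scale so a
    pipeline run on the fixtures exercises the normalization step.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise SimulationError(f"output directory {out} is not empty (use force=True)")
    study = simulate_study(design, seed)
    manifest = {"seed": int(seed), "files": {}}

    def _note(key, path):
        manifest["files"][key] = {"path": path.name, "sha256": mio.file_digest(path)}

    p = out / "paired_expression.tsv"
    mio.write_expression(study.paired_expr, p)
    _note("paired_expression", p)
    p = out / "pairing.tsv"
    mio.write_pairing(study.pairing, p)
    _note("pairing", p)
    truth_all = {"paired": study.truth_paired.to_dict()}
    for name, (expr, clin, truth) in study.cohorts.items():
        p = out / f"{name}_expression.tsv"
        mio.write_expression(to_linear_scale(expr), p)
        _note(f"{name}_expression", p)
        p = out / f"{name}_clinical.tsv"
        mio.write_clinical(clin, p)
        _note(f"{name}_clinical", p)
        truth_all[name] = truth.to_dict()
    p = out / "ground_truth.json"
    mio.write_json(truth_all, p)
    _note("ground_truth", p)
    mio.write_json(manifest, out / "fixture_manifest.json")
    return manifest
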