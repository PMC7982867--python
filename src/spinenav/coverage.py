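"""Ultrasound acquisition coverage of the vertebral anatomy and its models.

Coverage asks *what part of the vertebra the sweep actually imaged*.
Under the straight-ray, no-bone-penetration assumption, each image
column contributes at most one CT voxel: the first labelled voxel the
ray meets after mapping the column into CT space through the ground-truth
alignment.  Unique first-hit voxels are tallied into seven bins — the
five regions of the scanned level (SP, L, AP, TP, VB) plus the pooled
whole-vertebra bins of the directly inferior (Inf) and superior (Sup)
neighbors.  A voxel re-hit by many columns counts once: re-scanning the
same surface patch is not more coverage.

Two regression models relate coverage to outcome, mirroring the study's
grouping structure (acquisitions nested in vertebral levels, with
frequency and depth sub-groups per level):

* a linear mixed-effect model of TRE on the five label counts and their
  pairwise interactions, with a random intercept per level and variance
  components for frequency-within-level and depth-within-level;
* a binomial mixed-effect model of the level-mismatch indicator on the
  total own-level coverage (SP+L+AP+TP+VB).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

from . import raycast
from .evaluation import CLASS_MISMATCH, EvaluationConfig, TREResult
from .geometry import RigidTransform, compose
from .phantom import REGIONS, decode_label
from .ultrasound import TrackedSweep
from .volume import Volume

__all__ = [
    "COVERAGE_BINS",
    "CoverageHistogram",
    "CoverageModelFit",
    "compute_coverage",
    "build_accuracy_design",
    "build_misalignment_response",
    "fit_accuracy_model",
    "fit_mismatch_model",
]

LABELS = tuple(REGIONS)  # ("SP", "L", "AP", "TP", "VB")
COVERAGE_BINS = LABELS + ("Inf", "Sup")


@dataclass
class CoverageHistogram:
    """Unique first-hit voxel counts per bin for one acquisition."""

    level: int
    counts: dict[str, int]
    depth_cm: float | None = None
    frequency_mhz: float | None = None
    repetition: int | None = None

    def __post_init__(self) -> None:
        missing = [b for b in COVERAGE_BINS if b not in self.counts]
        if missing:
            raise ValueError(f"histogram lacks bins {missing}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("coverage counts must be non-negative")

    def own_level_total(self) -> int:
        """Sum over the five own-level labels, excluding Inf/Sup."""
        return sum(self.counts[b] for b in LABELS)


@dataclass
class CoverageModelFit:
    coefficients: pd.DataFrame  # columns: term, estimate, se, pvalue
    grouping: str
    converged: bool

    def term(self, name: str) -> pd.Series:
        row = self.coefficients[self.coefficients["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def compute_coverage(
    sweep: TrackedSweep,
    labelmap: Volume,
    reference_to_ct: RigidTransform,
    level: int | None = None,
    step_mm: float | None = None,
) -> CoverageHistogram:
    """First-voxel coverage histogram of one sweep against the labelmap.

    Every image column of every frame is marched from the probe face
    along its depth axis (mapped to CT via ``reference_to_ct`` composed
    with the frame pose); the first labelled voxel stops the ray.  Hits
    on the scanned level are binned by region; hits on the directly
    adjacent levels go to the pooled Inf (one level inferior, i.e. a
    larger level index) or Sup bins; hits on more distant levels stop the
    ray without being counted.  Counts are unique-voxel cardinalities.
    """
    lvl = level if level is not None else sweep.level
    if step_mm is None:
        step_mm = float(np.min(labelmap.spacing)) / 4.0
    cfg = sweep.config
    u = cfg.column_positions_mm()
    hit_sets: dict[str, set[tuple[int, int, int]]] = {b: set() for b in COVERAGE_BINS}
    for frame in sweep.frames:
        pose_ct = compose(reference_to_ct, frame.pose)
        origins = pose_ct.translation[None, :] + u[:, None] * pose_ct.rotation[:, 0][None, :]
        hits = raycast.first_hit(
            labelmap, origins, pose_ct.rotation[:, 1][None, :], step_mm, cfg.depth_mm
        )
        for vox, lab in zip(hits.voxel_index[hits.hit], hits.label[hits.hit]):
            hit_level, region = decode_label(int(lab))
            if hit_level == lvl:
                bin_name = LABELS[int(region) - 1]
            elif hit_level == lvl + 1:
                bin_name = "Inf"
            elif hit_level == lvl - 1:
                bin_name = "Sup"
            else:
                continue
            hit_sets[bin_name].add(tuple(int(i) for i in vox))
    return CoverageHistogram(
        level=lvl,
        counts={b: len(s) for b, s in hit_sets.items()},
        depth_cm=cfg.depth_cm,
        frequency_mhz=cfg.frequency_mhz,
    )


def _interaction_terms() -> list[tuple[str, str]]:
    return list(itertools.combinations(LABELS, 2))


def simulate_coverage_design(
    seed: int,
    beta_l_per_voxel: float = 0.0,
    n_levels: int = 6,
    repetitions: int = 5,
    level_sd: float = 0.2,
    subgroup_sd: float = 0.1,
    noise_sd: float = 0.3,
    baseline_mm: float = 1.5,
    mismatch_logit_slope: float = 0.0,
    mismatch_base_rate: float = 0.12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic coverage/outcome dataset under the study's grouping design.

    Generates the full acquisition grid (n_levels × 2 frequencies × 2
    depths × ``repetitions``) with coverage counts at magnitudes matching
    the reported histograms (AP highest, around 1500 voxels; L and SP
    around 1000; TP and VB only populated at 7 cm depth) and a TRE
    response ``baseline + beta_l * L + level effect + sub-group effects +
    noise``.  Also returns a binary mismatch table whose log-odds depend
    on the own-level coverage sum through ``mismatch_logit_slope`` (zero
    for a null model).  Used for parameter-recovery and type-I-error
    checks of the two coverage models.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lvl_eff = rng.normal(0.0, level_sd, size=n_levels)
    for li in range(n_levels):
        for fi, freq in enumerate((6.0, 12.0)):
            for di, depth in enumerate((5.0, 7.0)):
                sub_eff = rng.normal(0.0, subgroup_sd, size=2)
                for rep in range(repetitions):
                    cov = {
                        "SP": max(rng.normal(950, 250), 0.0),
                        "L": max(rng.normal(1000, 300), 0.0),
                        "AP": max(rng.normal(1500, 350), 0.0),
                        "TP": max(rng.normal(200, 80), 0.0) if depth == 7.0 else 0.0,
                        "VB": max(rng.normal(60, 40), 0.0) if depth == 7.0 else 0.0,
                    }
                    tre = (
                        baseline_mm
                        + beta_l_per_voxel * cov["L"]
                        + lvl_eff[li]
                        + sub_eff.sum()
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append(
                        {"level": li + 1, "frequency_mhz": freq, "depth_cm": depth,
                         "repetition": rep, "tre": max(tre, 0.0), **cov}
                    )
    df = pd.DataFrame(rows)
    for a, b in _interaction_terms():
        df[f"{a}:{b}"] = df[a] * df[b]

    cov_sum = df[list(LABELS)].sum(axis=1)
    centered = cov_sum - cov_sum.mean()
    logit = np.log(mismatch_base_rate / (1 - mismatch_base_rate)) + (
        mismatch_logit_slope * centered
    )
    lvl_logit = rng.normal(0.0, level_sd, size=n_levels)[df["level"] - 1]
    p = 1.0 / (1.0 + np.exp(-(logit + lvl_logit)))
    mism = pd.DataFrame(
        {"mismatch": (rng.uniform(size=len(df)) < p).astype(int),
         "coverage_sum": cov_sum,
         "level": df["level"], "depth_cm": df["depth_cm"],
         "frequency_mhz": df["frequency_mhz"]}
    )
    return df, mism


def build_accuracy_design(
    histograms: list[CoverageHistogram],
    results: list[TREResult],
    config: EvaluationConfig | None = None,
) -> pd.DataFrame:
    """Design table for the TRE-vs-coverage model.

    Level-mismatch acquisitions are removed first (they are outliers of a
    different failure mode, not accuracy variation).  Fixed-effect
    columns are the five label counts and their C(5,2) = 10 pairwise
    products; grouping columns carry the level and the frequency/depth
    sub-groups.  Rows with all-zero coverage are retained.
    """
    if len(histograms) != len(results):
        raise ValueError("need one histogram per result")
    rows = []
    for h, r in zip(histograms, results):
        if r.classification == CLASS_MISMATCH:
            continue
        row = {
            "tre": r.own_tre,
            "level": r.level,
            "depth_cm": r.depth_cm,
            "frequency_mhz": r.frequency_mhz,
        }
        for lab in LABELS:
            row[lab] = float(h.counts[lab])
        for a, b in _interaction_terms():
            row[f"{a}:{b}"] = float(h.counts[a]) * float(h.counts[b])
        rows.append(row)
    if not rows:
        raise ValueError("no acquisitions left after removing level mismatches")
    return pd.DataFrame(rows)


def build_misalignment_response(
    results: list[TREResult],
    histograms: list[CoverageHistogram],
    config: EvaluationConfig | None = None,
) -> pd.DataFrame:
    """Binary mismatch response and the own-level coverage-sum covariate.

    Response is 1 iff the acquisition's own-level TRE reaches the
    mismatch threshold (≥ 10 mm); the covariate sums the five own-level
    label counts, excluding the adjacent-level bins.
    """
    cfg = config or EvaluationConfig()
    if len(histograms) != len(results):
        raise ValueError("need one histogram per result")
    return pd.DataFrame(
        {
            "mismatch": int(r.own_tre >= cfg.mismatch_threshold_mm),
            "coverage_sum": h.own_level_total(),
            "level": r.level,
            "depth_cm": r.depth_cm,
            "frequency_mhz": r.frequency_mhz,
        }
        for r, h in zip(results, histograms)
    )


def _fixed_terms() -> list[str]:
    return list(LABELS) + [f"{a}:{b}" for a, b in _interaction_terms()]


def fit_accuracy_model(design: pd.DataFrame) -> CoverageModelFit:
    """Linear mixed model of TRE on coverage terms.

    Random intercept per vertebral level plus variance components for
    the frequency and depth sub-groups within each level.  Fixed-effect
    columns are standardized internally for conditioning and estimates
    are reported back on the original (per-voxel) scale.  A singular or
    non-converged fit is reported through the flag, not an exception.
    """
    terms = [t for t in _fixed_terms() if t in design.columns]
    y = design["tre"].to_numpy(float)
    x_raw = design[terms].to_numpy(float)
    scale = x_raw.std(axis=0, ddof=0)
    usable = scale > 1e-12
    scale_safe = np.where(usable, scale, 1.0)
    x = (x_raw - x_raw.mean(axis=0)) / scale_safe
    exog = sm.add_constant(x[:, usable], has_constant="add")
    used_terms = [t for t, u in zip(terms, usable) if u]

    groups = design["level"].to_numpy()
    vc = {
        "frequency": pd.get_dummies(design["frequency_mhz"]).to_numpy(float),
        "depth": pd.get_dummies(design["depth_cm"]).to_numpy(float),
    }
    converged = True
    if np.std(y) < 1e-12 or not used_terms:
        # degenerate response: slopes are exactly zero
        coefs = pd.DataFrame(
            {"term": terms, "estimate": 0.0, "se": np.nan, "pvalue": np.nan}
        )
        return CoverageModelFit(coefs, "level / (frequency, depth)", True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=groups, exog_vc=_vc_design(vc, groups))
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError):
        return CoverageModelFit(
            pd.DataFrame({"term": terms, "estimate": np.nan, "se": np.nan, "pvalue": np.nan}),
            "level / (frequency, depth)",
            False,
        )
    est = np.full(len(terms), 0.0)
    se = np.full(len(terms), np.nan)
    pv = np.full(len(terms), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe = res.fe_params[1: 1 + len(used_terms)]
        fe_se = res.bse_fe[1: 1 + len(used_terms)]
        fe_p = res.pvalues[1: 1 + len(used_terms)]
    for k, t in enumerate(used_terms):
        i = terms.index(t)
        s = scale_safe[terms.index(t)]
        est[i] = fe[k] / s
        se[i] = fe_se[k] / s
        pv[i] = fe_p[k]
    coefs = pd.DataFrame({"term": terms, "estimate": est, "se": se, "pvalue": pv})
    return CoverageModelFit(coefs, "level / (frequency, depth)", converged)


def _vc_design(vc: dict[str, np.ndarray], groups: np.ndarray):
    """Per-group variance-component design in MixedLM's nested-dict form."""
    from statsmodels.regression.mixed_linear_model import VCSpec

    names = list(vc)
    colnames = []
    mats = []
    ulevels = pd.unique(groups)
    for name in names:
        mat = vc[name]
        colnames.append([[f"{name}{j}" for j in range(mat.shape[1])] for _ in ulevels])
        mats.append([mat[groups == g] for g in ulevels])
    return VCSpec(names, colnames, mats)


def fit_mismatch_model(df: pd.DataFrame) -> CoverageModelFit:
    """Binomial mixed model of the mismatch indicator on coverage sum.

    Logistic regression with a random intercept per level and variance
    components for the frequency and depth sub-groups, fitted by the
    variational-Bayes routine for binomial mixed GLMs.  The covariate is
    centered before fitting (slope invariant to covariate shifts).
    Complete separation is flagged as non-converged rather than raised.
    """
    y = df["mismatch"].to_numpy(float)
    cov = df["coverage_sum"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative response")
    xc = cov - cov.mean()

    # complete-separation screen on the single covariate
    pos, neg = xc[y == 1], xc[y == 0]
    separated = pos.min() > neg.max() or pos.max() < neg.min()

    exog = sm.add_constant(xc / max(xc.std(), 1e-12))
    groups = df["level"].to_numpy()
    ulev = pd.unique(groups)
    vc_cols = [
        pd.get_dummies(groups).to_numpy(float),
        pd.get_dummies(list(zip(groups, df["frequency_mhz"]))).to_numpy(float),
        pd.get_dummies(list(zip(groups, df["depth_cm"]))).to_numpy(float),
    ]
    exog_vc = np.hstack(vc_cols)
    ident = np.concatenate([np.full(m.shape[1], k) for k, m in enumerate(vc_cols)])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM(y, exog, exog_vc, ident)
            res = model.fit_vb()
        slope = res.fe_mean[1] / max(xc.std(), 1e-12)
        sd = res.fe_sd[1] / max(xc.std(), 1e-12)
        z = res.fe_mean[1] / res.fe_sd[1]
        from scipy import stats

        pvalue = 2 * stats.norm.sf(abs(z))
    except (np.linalg.LinAlgError, ValueError):
        slope, sd, pvalue, converged = np.nan, np.nan, np.nan, False
    if separated:
        converged = False
    coefs = pd.DataFrame(
        {"term": ["coverage_sum"], "estimate": [slope], "se": [sd], "pvalue": [pvalue]}
    )
    return CoverageModelFit(coefs, "level / (frequency, depth)", converged)
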