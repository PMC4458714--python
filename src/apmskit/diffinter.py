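"""Beta-binomial differential interaction scoring.

Each protein's spectral counts are modeled as beta-binomial draws out of
per-sample totals.  Interactors are called by a likelihood-ratio test of a
common success fraction against group-specific fractions (overdispersion
shared), with Benjamini-Hochberg adjustment across proteins.  Treatment
effects are classified after rescaling treatment counts so the bait
protein's counts match the untreated reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .counts import CountExperiment

logger = logging.getLogger(__name__)

_EPS_PI = 1e-9
_THETA_MAX = 0.999
_THETA_SWITCH = 1e-9  # below this, use the binomial limit
_XATOL = 1e-8

TREATMENT_ALIASES = {
    "msl2kd": "bait_msl2kd",
    "rnase": "bait_rnase",
    "bait_msl2kd": "bait_msl2kd",
    "bait_rnase": "bait_rnase",
}


@dataclass
class BetaBinModel:
    """Mean/overdispersion parameterization of the beta-binomial.

    ``pi`` is the mean success fraction alpha/(alpha+beta) and ``theta`` the
    overdispersion 1/(alpha+beta+1); theta -> 0 recovers the binomial.
    """

    pi: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if self.theta < 0.0:
            raise ValueError("theta must be >= 0")

    @property
    def alpha(self) -> float:
        return self.pi * (1.0 - self.theta) / self.theta

    @property
    def beta(self) -> float:
        return (1.0 - self.pi) * (1.0 - self.theta) / self.theta

    @classmethod
    def from_shapes(cls, alpha: float, beta: float) -> "BetaBinModel":
        if alpha <= 0 or beta <= 0:
            raise ValueError("shape parameters must be positive")
        return cls(pi=alpha / (alpha + beta), theta=1.0 / (alpha + beta + 1.0))


def betabin_logpmf(x, n, alpha: float, beta: float):
    """log P(X = x) for X ~ BetaBinomial(n, alpha, beta).

    Computed as log[C(n, x) B(x + alpha, n - x + beta) / B(alpha, beta)];
    vectorized over x and n.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    return (
        special.gammaln(n + 1)
        - special.gammaln(x + 1)
        - special.gammaln(n - x + 1)
        + special.betaln(x + alpha, n - x + beta)
        - special.betaln(alpha, beta)
    )


def _logpmf_const(x: np.ndarray, n: np.ndarray) -> float:
    """Binomial-coefficient terms, independent of (pi, theta)."""
    return float(
        (special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)).sum()
    )


def _kernel_loglik(x: np.ndarray, n: np.ndarray, pi: float, theta: float) -> float:
    """Log-likelihood without the (pi, theta)-independent coefficient terms."""
    if theta < _THETA_SWITCH:
        return float((x * math.log(pi) + (n - x) * math.log1p(-pi)).sum())
    a = pi * (1.0 - theta) / theta
    b = (1.0 - pi) * (1.0 - theta) / theta
    return float(special.betaln(x + a, n - x + b).sum()) - len(x) * float(
        special.betaln(a, b)
    )


def _loglik(x: np.ndarray, n: np.ndarray, pi: float, theta: float) -> float:
    return _kernel_loglik(x, n, pi, theta) + _logpmf_const(x, n)


def _fit_pi(x: np.ndarray, n: np.ndarray, theta: float) -> tuple[float, float]:
    """MLE of pi at fixed theta; returns (pi_hat, kernel loglik)."""
    res = optimize.minimize_scalar(
        lambda p: -_kernel_loglik(x, n, p, theta),
        bounds=(_EPS_PI, 1.0 - _EPS_PI),
        method="bounded",
        options={"xatol": _XATOL},
    )
    return float(res.x), float(-res.fun)


def fit_betabin(x, n, theta: float | None = None) -> tuple[BetaBinModel, float]:
    """Maximum-likelihood fit of a single beta-binomial to counts/totals.

    If ``theta`` is given it is held fixed; otherwise the likelihood is
    profiled over theta by bounded one-dimensional optimization.  Returns
    the fitted model and its log-likelihood.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("per-sample totals must be positive")

    const = _logpmf_const(x, n)
    if theta is not None:
        pi, ll = _fit_pi(x, n, theta)
        return BetaBinModel(pi=pi, theta=max(theta, _THETA_SWITCH)), ll + const

    def profile(t: float) -> float:
        return -_fit_pi(x, n, t)[1]

    res = optimize.minimize_scalar(
        profile, bounds=(0.0, _THETA_MAX), method="bounded", options={"xatol": _XATOL}
    )
    t_hat = float(res.x)
    pi_hat, ll = _fit_pi(x, n, t_hat)
    return BetaBinModel(pi=pi_hat, theta=max(t_hat, _THETA_SWITCH)), ll + const


def bb_test(
    counts_a, totals_a, counts_b, totals_b, theta: float | None = None
) -> tuple[float, int]:
    """Likelihood-ratio test of equal success fractions in two groups.

    Null: one common pi; alternative: group-specific pi_a, pi_b; the
    overdispersion theta is shared within each hypothesis and profiled out
    (or held fixed when given).  The p-value comes from chi-square with one
    degree of freedom; direction is sign(pi_a_hat - pi_b_hat).
    """
    xa = np.asarray(counts_a, dtype=float)
    na = np.asarray(totals_a, dtype=float)
    xb = np.asarray(counts_b, dtype=float)
    nb = np.asarray(totals_b, dtype=float)
    if xa.size + xb.size < 2:
        raise ValueError("need at least 2 samples overall")
    if np.any(na <= 0) or np.any(nb <= 0):
        raise ValueError("per-sample totals must be positive")
    if xa.sum() == 0 and xb.sum() == 0:
        return 1.0, 0

    x_all = np.concatenate([xa, xb])
    n_all = np.concatenate([na, nb])

    def ll_null(t: float) -> float:
        return _fit_pi(x_all, n_all, t)[1]

    def ll_alt(t: float) -> float:
        return _fit_pi(xa, na, t)[1] + _fit_pi(xb, nb, t)[1]

    if theta is not None:
        t0 = t1 = theta
    else:
        t0 = float(
            optimize.minimize_scalar(
                lambda t: -ll_null(t), bounds=(0.0, _THETA_MAX), method="bounded",
                options={"xatol": _XATOL},
            ).x
        )
        t1 = float(
            optimize.minimize_scalar(
                lambda t: -ll_alt(t), bounds=(0.0, _THETA_MAX), method="bounded",
                options={"xatol": _XATOL},
            ).x
        )
    l0 = ll_null(t0)
    l1 = ll_alt(t1)
    pi_a, _ = _fit_pi(xa, na, t1)
    pi_b, _ = _fit_pi(xb, nb, t1)
    stat = max(0.0, 2.0 * (l1 - l0))
    p = float(stats.chi2.sf(stat, df=1))
    direction = int(np.sign(pi_a - pi_b))
    return p, direction


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# interactor calling

@dataclass
class InteractorCall:
    group_id: str
    p_value: float
    q_value: float
    confident: bool
    direction: int
    treatment_effects: dict[str, tuple[str, float]] = field(default_factory=dict)


def _rounded_matrix(experiment: CountExperiment) -> pd.DataFrame:
    if experiment.corrected_counts is None:
        raise ValueError("experiment lacks corrected counts; run split_shared first")
    # half-up rounding for the count likelihood; raw reals kept upstream
    return np.floor(experiment.corrected_counts + 0.5).astype(int)


def call_interactors(
    experiment: CountExperiment,
    fdr_cut: float = 0.2,
    two_sided_only: bool = False,
) -> list[InteractorCall]:
    """Beta-binomial test of bait vs pooled controls, BH-adjusted.

    Empty-vector and GFP control samples are pooled as control replicates.
    A call is confident when q < ``fdr_cut`` and (unless
    ``two_sided_only``) the bait fraction exceeds the control fraction.
    Proteins with zero counts in every tested sample are skipped.
    """
    mat = _rounded_matrix(experiment)
    bait_samples = experiment.samples_for("bait")
    ctrl_samples = experiment.samples_for("control_empty", "control_gfp")
    if not bait_samples:
        raise ValueError("no bait samples in experiment")
    if len(ctrl_samples) < 2:
        raise ValueError("need at least 2 control samples")
    totals = mat.sum(axis=0)
    na = totals[bait_samples].to_numpy()
    nb = totals[ctrl_samples].to_numpy()

    tested: list[str] = []
    pvals: list[float] = []
    dirs: list[int] = []
    for gid in mat.index:
        xa = mat.loc[gid, bait_samples].to_numpy()
        xb = mat.loc[gid, ctrl_samples].to_numpy()
        if xa.sum() == 0 and xb.sum() == 0:
            continue
        p, d = bb_test(xa, na, xb, nb)
        tested.append(gid)
        pvals.append(p)
        dirs.append(d)

    qvals = bh_adjust(pvals)
    calls = []
    for gid, p, q, d in zip(tested, pvals, qvals, dirs):
        confident = q < fdr_cut and (two_sided_only or d > 0)
        calls.append(
            InteractorCall(
                group_id=gid, p_value=p, q_value=float(q), confident=confident,
                direction=d,
            )
        )
    return calls


def normalize_by_bait(
    experiment: CountExperiment, condition: str
) -> tuple[pd.DataFrame, float]:
    """Scale a treatment condition's counts to the reference bait level.

    The factor is the bait protein's mean count per untreated bait sample
    divided by its mean count per sample of the condition;
    the condition's columns of the corrected-count matrix are multiplied by
    it, so the bait rows agree after scaling.
    """
    condition = TREATMENT_ALIASES.get(condition, condition)
    mat = (
        experiment.corrected_counts
        if experiment.corrected_counts is not None
        else experiment.unique_counts.astype(float)
    ).copy()
    bait = experiment.bait_accession
    if bait not in mat.index:
        raise ValueError(f"bait accession {bait!r} absent from count matrix")
    ref_samples = experiment.samples_for("bait")
    cond_samples = experiment.samples_for(condition)
    if not cond_samples:
        raise ValueError(f"no samples with condition {condition!r}")
    ref_bait = float(mat.loc[bait, ref_samples].mean())
    cond_bait = float(mat.loc[bait, cond_samples].mean())
    if cond_bait <= 0:
        raise ValueError(
            f"bait protein has zero counts in condition {condition!r}; cannot normalize"
        )
    if ref_bait <= 0:
        raise ValueError("bait protein has zero counts in the reference samples")
    factor = ref_bait / cond_bait
    mat[cond_samples] = mat[cond_samples] * factor
    return mat, factor


def classify_treatment(
    experiment: CountExperiment,
    treatment: str,
    alpha: float = 0.05,
    expression_ratios: Mapping[str, float] | None = None,
    interactors: Sequence[str] | None = None,
) -> dict[str, tuple[str, float]]:
    """Label each interactor Increase/Decrease/none under a treatment.

    Treatment counts are first bait-normalized (see
    :func:`normalize_by_bait`), which places them on the reference scale;
    their trial totals are therefore the mean reference column total (a
    scaled column's own sum would cancel the normalization, and the raw sum
    would invert it).  When ``expression_ratios`` maps a protein to its
    expression fold-change under the treatment, that protein's treatment
    counts are divided by the fold-change before testing (missing ratios
    are logged and left uncorrected).  Labels follow the test direction at
    significance ``alpha``.
    """
    condition = TREATMENT_ALIASES.get(treatment, treatment)
    scaled, factor = normalize_by_bait(experiment, condition)
    raw = _rounded_matrix(experiment)
    ref_samples = experiment.samples_for("bait")
    cond_samples = experiment.samples_for(condition)
    totals = raw.sum(axis=0)
    na = totals[ref_samples].to_numpy()
    nb = np.full(len(cond_samples), int(round(na.mean())))

    if interactors is None:
        interactors = [c.group_id for c in call_interactors(experiment) if c.confident]

    out: dict[str, tuple[str, float]] = {}
    for gid in interactors:
        if gid not in scaled.index:
            logger.warning("interactor %r absent from count matrix; skipped", gid)
            continue
        xa = raw.loc[gid, ref_samples].to_numpy()
        xb = scaled.loc[gid, cond_samples].to_numpy()
        if expression_ratios is not None:
            fc = expression_ratios.get(gid)
            if fc is None:
                logger.warning("no expression ratio for %r; left uncorrected", gid)
            elif fc <= 0:
                raise ValueError(f"non-positive expression fold-change for {gid!r}")
            else:
                xb = xb / fc
        xb = np.floor(xb + 0.5).astype(int)
        if xa.sum() == 0 and xb.sum() == 0:
            out[gid] = ("none", 1.0)
            continue
        p, d = bb_test(xa, na, xb, nb)
        if p < alpha and d > 0:
            label = "Decrease"
        elif p < alpha and d < 0:
            label = "Increase"
        else:
            label = "none"
        out[gid] = (label, p)
    return out


def calls_to_table(calls: Sequence[InteractorCall]) -> pd.DataFrame:
    treatments = sorted({t for c in calls for t in c.treatment_effects})
    rows = []
    for c in calls:
        row = {
            "group_id": c.group_id,
            "p_value": c.p_value,
            "q_value": c.q_value,
            "confident": c.confident,
            "direction": c.direction,
        }
        for t in treatments:
            label, p = c.treatment_effects.get(t, ("", float("nan")))
            row[f"effect_{t}"] = label
            row[f"p_{t}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def read_expression_ratios(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene id, fold-change) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    gene_col, fc_col = df.columns[:2]
    return dict(zip(df[gene_col].astype(str), df[fc_col].astype(float)))


def load_interactor_annotations() -> pd.DataFrame:
    """Packaged annotation table of bait interactors with nucleic-acid roles.

    Columns: protein_description, biological_process, msl2kd_effect,
    rnase_effect (effects restricted to Decrease/Increase/blank).
    """
    ref = resources.files("apmskit").joinpath("data/nucleic_acid_interactors.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    allowed = {"Decrease", "Increase", ""}
    for col in ("msl2kd_effect", "rnase_effect"):
        bad = set(df[col]) - allowed
        if bad:
            raise ValueError(f"unexpected effect labels in fixture: {bad}")
    return df
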