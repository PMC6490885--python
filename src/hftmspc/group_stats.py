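"""Group-level aggregation and mixed-model contrasts of coherence values.

Per-channel coherence values are averaged over the two second-order IM
components and restricted to a fixed 17-electrode posterior region of
interest (all occipital, parieto-occipital and parietal electrodes),
keeping channel as a factor.  Condition effects are then tested with
linear mixed-effects models fitted by maximum likelihood and compared via
likelihood-ratio tests: chi2 = 2*(ll_full - ll_reduced) on as many
degrees of freedom as fixed-effect parameters were dropped.

Coherence values live in [0, 1], where near-boundary data can make mixed
models misbehave at small n; a participant-level sign-flip permutation
contrast is provided as a robust alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ROIDefinition",
    "POSTERIOR_ROI_17",
    "LRTResult",
    "InteractionResult",
    "ModelConvergenceError",
    "roi_aggregate",
    "lrt_contrast",
    "interaction_analysis",
    "median_split",
    "permutation_contrast",
]


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")


#: occipital (3) + parieto-occipital (5) + parietal (9) = 17 electrodes
POSTERIOR_ROI_17 = ROIDefinition(
    "posterior17",
    (
        "Oz", "O1", "O2",
        "POz", "PO3", "PO4", "PO7", "PO8",
        "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    ),
)


class ModelConvergenceError(RuntimeError):
    """A mixed model failed to converge; carries the fitting diagnostics."""


def roi_aggregate(
    results: pd.DataFrame,
    roi: ROIDefinition,
    im_pair: tuple[float, float],
    value: str = "value",
) -> pd.DataFrame:
    """Average the two second-order IM components within the ROI.

    ``results`` is long-format with at least (participant, channel, freq,
    value) plus condition columns.  The output keeps one row per
    participant x channel x condition cell with the pair-averaged value;
    channel remains a factor for model nesting.
    """
    missing = [lab for lab in roi.labels if lab not in set(results["channel"])]
    if missing:
        raise ValueError(f"ROI channels absent from the results table: {missing}")
    sel = results[results["channel"].isin(roi.labels)].copy()
    sel = sel[np.isclose(sel["freq"].values[:, None], np.asarray(im_pair)).any(axis=1)]
    if sel.empty:
        raise ValueError(f"no rows at the IM frequencies {im_pair}")
    keys = [c for c in sel.columns if c not in {value, "freq"}]
    out = sel.groupby(keys, as_index=False, observed=True)[value].mean()
    if ((out[value] < 0) | (out[value] > 1)).any():
        raise ValueError("coherence values outside [0, 1]")
    return out


def _fit_ml(formula: str, table: pd.DataFrame, groups: str,
            re_formula: str | None, vc_formula: dict | None):
    model = smf.mixedlm(
        formula, table, groups=table[groups],
        re_formula=re_formula, vc_formula=vc_formula,
    )
    boundary = False
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = model.fit(reml=False, method=method, maxiter=200)
            boundary = any(issubclass(w.category, ConvergenceWarning) for w in caught)
            if fit.converged:
                return fit, boundary
        except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
            last_err = err
    raise ModelConvergenceError(
        f"mixed model {formula!r} did not converge (last error: {last_err})"
    )


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    dropped_term: str
    ll_full: float
    ll_reduced: float
    singular_fit: bool  # a variance parameter hit the boundary in either fit


def lrt_contrast(
    table: pd.DataFrame,
    full_terms: list[str],
    dropped_term: str,
    value: str = "value",
    groups: str = "participant",
    re_formula: str | None = None,
    vc_formula: dict | None = None,
) -> LRTResult:
    """Likelihood-ratio test for one fixed-effect term.

    Both models are fitted by maximum likelihood on the same rows; the
    reduced model drops ``dropped_term`` from ``full_terms``.  The degrees
    of freedom equal the number of fixed-effect parameters removed.
    """
    if dropped_term not in full_terms:
        raise ValueError(f"{dropped_term!r} is not among the full model terms")
    reduced_terms = [t for t in full_terms if t != dropped_term] or ["1"]
    f_full = f"{value} ~ {' + '.join(full_terms)}"
    f_reduced = f"{value} ~ {' + '.join(reduced_terms)}"
    # degenerate design: a dropped term whose column is identically zero
    # cannot change the likelihood (and makes the full fit singular)
    try:
        col = np.ones(len(table))
        for part in dropped_term.split(":"):
            col = col * table[part].to_numpy(dtype=float)
        degenerate = np.ptp(col) == 0.0 and col[0] == 0.0
    except (KeyError, ValueError, TypeError):
        degenerate = False
    if degenerate:
        fit_red, b2 = _fit_ml(f_reduced, table, groups, re_formula, vc_formula)
        return LRTResult(
            chi2=0.0, df=1, p=1.0, dropped_term=dropped_term,
            ll_full=float(fit_red.llf), ll_reduced=float(fit_red.llf), singular_fit=b2,
        )
    fit_full, b1 = _fit_ml(f_full, table, groups, re_formula, vc_formula)
    fit_red, b2 = _fit_ml(f_reduced, table, groups, re_formula, vc_formula)
    df = fit_full.k_fe - fit_red.k_fe
    chi2 = max(2.0 * (fit_full.llf - fit_red.llf), 0.0)
    return LRTResult(
        chi2=float(chi2),
        df=int(df),
        p=float(sps.chi2.sf(chi2, df)),
        dropped_term=dropped_term,
        ll_full=float(fit_full.llf),
        ll_reduced=float(fit_red.llf),
        singular_fit=b1 or b2,
    )


def median_split(levels: np.ndarray) -> np.ndarray:
    """Boolean mask of the upper (``expected``) half of graded levels.

    The split is at the median of the distinct levels; values strictly
    above it are 'expected'.  With four ordered levels this yields
    {1, 2} vs {3, 4}.
    """
    levels = np.asarray(levels, dtype=float)
    med = np.median(np.unique(levels))
    return levels > med


@dataclass
class InteractionResult:
    interaction: LRTResult
    expectation_within_attended: LRTResult
    attention_within_expected: LRTResult
    slope_attended: tuple[float, float]    # (estimate, p)
    slope_unattended: tuple[float, float]


def interaction_analysis(
    table: pd.DataFrame,
    value: str = "value",
    expectation: str = "expectation",
    attention: str = "attention",
    groups: str = "participant",
    re_formula: str | None = None,
    vc_formula: dict | None = None,
) -> InteractionResult:
    """Expectation x attention interaction model with the stated posthocs.

    ``expectation`` must be graded (>= 3 ordered numeric levels) and
    ``attention`` binary (0 = unattended, 1 = attended).  Fits the full
    interaction model, tests the interaction term by LRT, then: the
    expectation effect within the attended rows; the attention effect
    within the 'expected' half of a median split; and the per-condition
    expectation slopes (Wald estimate and p).
    """
    exp_levels = np.unique(table[expectation])
    if len(exp_levels) < 3:
        raise ValueError("graded expectation requires >= 3 levels")
    if len(np.unique(table[attention])) < 2:
        raise ValueError("attention requires 2 levels")

    inter = f"{expectation}:{attention}"
    terms = [expectation, attention, inter]
    interaction = lrt_contrast(table, terms, inter, value, groups, re_formula, vc_formula)

    attended = table[table[attention] == 1]
    exp_within_att = lrt_contrast(
        attended, [expectation], expectation, value, groups, re_formula, vc_formula
    )

    expected_rows = table[median_split(table[expectation].values)]
    att_within_exp = lrt_contrast(
        expected_rows, [attention], attention, value, groups, re_formula, vc_formula
    )

    slopes = {}
    for level, name in ((1, "attended"), (0, "unattended")):
        sub = table[table[attention] == level]
        fit, _ = _fit_ml(f"{value} ~ {expectation}", sub, groups, re_formula, vc_formula)
        slopes[name] = (float(fit.params[expectation]), float(fit.pvalues[expectation]))

    return InteractionResult(
        interaction=interaction,
        expectation_within_attended=exp_within_att,
        attention_within_expected=att_within_exp,
        slope_attended=slopes["attended"],
        slope_unattended=slopes["unattended"],
    )


def simulate_contrast_table(
    n_participants: int = 15,
    n_channels: int = 4,
    effect: float = 0.0,
    baseline: float = 0.3,
    intercept_sd: float = 0.05,
    slope_sd: float = 0.05,
    noise_sd: float = 0.05,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """A two-condition table from the mixed model's own generative process.

    value = baseline + u_p + (effect + s_p) * condition + noise, with
    participant intercepts u_p ~ N(0, intercept_sd^2), participant slopes
    s_p ~ N(0, slope_sd^2) and residual noise per channel row.  Used to
    calibrate the likelihood-ratio test (type-I error, power).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0.0, intercept_sd)
        s = rng.normal(0.0, slope_sd)
        for cond in (0, 1):
            eps = rng.normal(0.0, noise_sd, n_channels)
            for c in range(n_channels):
                rows.append(
                    {
                        "participant": f"P{p:02d}",
                        "channel": f"ch{c}",
                        "condition": cond,
                        "value": baseline + u + (effect + s) * cond + eps[c],
                    }
                )
    return pd.DataFrame(rows)


def simulate_interaction_table(
    n_participants: int = 15,
    n_channels: int = 2,
    slope_attended: float = 0.0,
    slope_unattended: float = 0.0,
    baseline: float = 0.3,
    intercept_sd: float = 0.05,
    noise_sd: float = 0.05,
    n_expectation_levels: int = 4,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """A graded-expectation x binary-attention table.

    Expectation levels are 1..n (scaled to [0, 1] in the predictor); each
    attention condition has its own expectation slope, so unequal slopes
    inject a true interaction.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    levels = np.arange(1, n_expectation_levels + 1)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0.0, intercept_sd)
        for att, slope in ((1, slope_attended), (0, slope_unattended)):
            for lev in levels:
                x = (lev - 1) / (n_expectation_levels - 1)
                for c in range(n_channels):
                    rows.append(
                        {
                            "participant": f"P{p:02d}",
                            "channel": f"ch{c}",
                            "expectation": lev,
                            "attention": att,
                            "value": baseline + u + slope * x + rng.normal(0.0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def permutation_contrast(
    table: pd.DataFrame,
    condition: str,
    value: str = "value",
    participant: str = "participant",
    n_flips: int = 10000,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Participant-level sign-flip test of a two-condition difference.

    Returns ``(mean_difference, p)`` where the difference is condition
    level 1 minus level 0 averaged within participants first, and p is the
    two-sided sign-flip permutation probability.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    levels = np.sort(table[condition].unique())
    if len(levels) != 2:
        raise ValueError("permutation contrast requires exactly two condition levels")
    per = table.groupby([participant, condition], observed=True)[value].mean().unstack(condition)
    diffs = (per[levels[1]] - per[levels[0]]).dropna().values
    obs = diffs.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_flips, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_flips + 1.0)
    return float(obs), float(p)
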