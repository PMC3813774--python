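"""Litter-aware group statistics with step-down Šidák adjustment.

Pups of the same dam are correlated, so the litter — not the pup — is the
independent statistical unit.  The primary inference here collapses pups to
per-(litter, genotype) means ("litter summaries") and tests factor effects
by permutation at the exchangeable level: treatment labels are permuted
across whole litters, genotype labels within litters, and the interaction
by permuting residuals of the additive litter-summary model.  A delegated
mixed-model mode (random litter intercept, via statsmodels) is available
for comparison.

Multiple comparisons across pairwise contrasts are adjusted with the
step-down Šidák procedure: order the raw p-values ascending, set
adjusted_(i) = 1 − (1 − p_(i))^(m − i + 1), enforce monotonicity along the
ordered sequence, and return in the original order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import FetusRecord

logger = logging.getLogger("fgrtools")

DEFAULT_N_PERM = 9999


# ---------------------------------------------------------------------------
# litter summaries


def fetuses_to_frame(fetuses: Iterable[FetusRecord]) -> pd.DataFrame:
    rows = [vars(f).copy() for f in fetuses]
    if not rows:
        raise ValueError("no fetus records")
    return pd.DataFrame(rows)


def litter_summaries(
    fetuses: Iterable[FetusRecord] | pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """One mean per (litter, genotype): columns litter_id, genotype,
    treatment, value, n_pups.  A litter missing a genotype contributes only
    to the cell it has pups in."""
    df = (
        fetuses
        if isinstance(fetuses, pd.DataFrame)
        else fetuses_to_frame(fetuses)
    )
    if endpoint not in df.columns:
        raise KeyError(f"endpoint {endpoint!r} not present on fetus records")
    vals = pd.to_numeric(df[endpoint], errors="coerce")
    df = df.assign(_value=vals).dropna(subset=["_value"])
    out = (
        df.groupby(["litter_id", "genotype", "treatment"], sort=False)
        .agg(value=("_value", "mean"), n_pups=("_value", "size"))
        .reset_index()
    )
    return out


def cell_stats(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cell mean ± SEM over litter summaries (litter is the unit of n)."""
    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    return (
        summaries.groupby(["genotype", "treatment"], sort=False)
        .agg(
            mean=("value", "mean"),
            sem=("value", _sem),
            n_litters=("value", "size"),
            n_pups=("n_pups", "sum"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class PermutationResult:
    p: float
    statistic: float
    n_perm: int
    factor: str


def _mean_diff(values: np.ndarray, mask: np.ndarray) -> float:
    return float(values[mask].mean() - values[~mask].mean())


def permutation_test(
    summaries: pd.DataFrame,
    factor: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test of a main effect on litter summaries.

    The test statistic is the difference of level means of the summaries.
    ``factor="treatment"`` permutes treatment labels across whole litters
    (litters are exchangeable under the null); ``factor="genotype"`` permutes
    genotype labels within each litter (the within-litter WT/P0 assignment is
    exchangeable).  p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm).
    """
    if factor not in ("treatment", "genotype"):
        raise ValueError("factor must be 'treatment' or 'genotype'")
    rng = np.random.default_rng(seed)
    y = summaries["value"].to_numpy(dtype=float)
    labels = summaries[factor].to_numpy()
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} needs exactly 2 levels, got {levels}")
    for lev in levels:
        if summaries.loc[labels == lev, "litter_id"].nunique() < 2:
            raise ValueError(f"need >= 2 litters per level of {factor!r}")
    mask = labels == levels[0]
    t_obs = _mean_diff(y, mask)

    if factor == "treatment":
        # permute litter-level labels; a litter's summaries move together
        litter_ids, litter_idx = np.unique(
            summaries["litter_id"].to_numpy(), return_inverse=True
        )
        litter_label = np.empty(len(litter_ids), dtype=bool)
        litter_label[litter_idx] = mask  # consistent within litter
        perms = np.tile(litter_label, (n_perm, 1))
        perms = rng.permuted(perms, axis=1)
        perm_mask = perms[:, litter_idx]  # (n_perm, n_summaries)
    else:
        # flip the genotype labels of each litter's summary pair with p=1/2;
        # litters carrying a single genotype keep their label
        litter_ids, litter_idx = np.unique(
            summaries["litter_id"].to_numpy(), return_inverse=True
        )
        counts = np.bincount(litter_idx)
        flippable = counts[litter_idx] == 2
        flips = rng.random((n_perm, len(litter_ids))) < 0.5
        flip_here = flips[:, litter_idx] & flippable[None, :]
        perm_mask = np.where(flip_here, ~mask[None, :], mask[None, :])

    # vectorised difference of level means across permutations
    n1 = perm_mask.sum(axis=1)
    n_tot = len(y)
    degenerate = (n1 == 0) | (n1 == n_tot)
    n1 = np.where(degenerate, 1, n1)  # avoid 0/0; flagged rows count as extreme
    s1 = perm_mask @ y
    t_perm = s1 / n1 - (y.sum() - s1) / (n_tot - n1)
    t_perm = np.where(degenerate, np.inf, t_perm)
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(p=float(p), statistic=t_obs, n_perm=n_perm, factor=factor)


def interaction_permutation_test(
    summaries: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """Genotype × treatment interaction via permutation of residuals from
    the additive litter-summary model (an approximate test: residuals are
    exchangeable only asymptotically)."""
    rng = np.random.default_rng(seed)
    y = summaries["value"].to_numpy(dtype=float)
    g = (summaries["genotype"].to_numpy() == summaries["genotype"].iloc[0])
    t = (summaries["treatment"].to_numpy() == summaries["treatment"].iloc[0])
    X = np.column_stack([np.ones_like(y), g.astype(float), t.astype(float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted

    def t_int(values: np.ndarray) -> float:
        means = {}
        for gg in (True, False):
            for tt in (True, False):
                sel = (g == gg) & (t == tt)
                if not sel.any():
                    return np.nan
                means[(gg, tt)] = values[sel].mean()
        return (means[(True, True)] - means[(True, False)]) - (
            means[(False, True)] - means[(False, False)]
        )

    t_obs = t_int(y)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_stats[i] = t_int(fitted + rng.permutation(resid))
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(t_obs) - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(
        p=float(p), statistic=float(t_obs), n_perm=n_perm, factor="interaction"
    )


# ---------------------------------------------------------------------------
# multiple comparisons


def sequential_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Šidák adjustment, returned in the original order.

    Ordered ascending, adjusted_(i) = 1 − (1 − p_(i))^(m − i + 1), with
    monotone non-decreasing enforcement along the ordered sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# derived endpoints and simple tests


def fetal_placental_ratio(
    fetuses: Iterable[FetusRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pup fetal:placental weight ratio and its per-cell summary
    (mean of pup ratios; SEM over litter means of the ratio).

    Pups with non-positive placental weight become error rows (ratio NaN)
    rather than aborting the batch.
    """
    df = (
        fetuses.copy()
        if isinstance(fetuses, pd.DataFrame)
        else fetuses_to_frame(fetuses)
    )
    bad = df["placental_weight"] <= 0
    if bad.any():
        logger.warning("fetal_placental_ratio: %d pup(s) with non-positive "
                       "placental weight", int(bad.sum()))
    df["fp_ratio"] = np.where(
        bad, np.nan, df["fetal_weight"] / df["placental_weight"]
    )
    per_pup = df[["fetus_id", "litter_id", "genotype", "treatment", "fp_ratio"]]
    summaries = litter_summaries(df.dropna(subset=["fp_ratio"]), "fp_ratio")
    return per_pup, cell_stats(summaries)


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Welch unpaired two-sided t test (delegated to scipy)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(res.statistic):  # zero variance in both groups, equal means
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full group comparison


@dataclass
class GroupComparison:
    """Litter-aware comparison of one endpoint across the 2×2 design."""

    endpoint: str
    cells: pd.DataFrame = field(repr=False)  # mean, sem, n_litters, n_pups
    p_genotype: float
    p_treatment: float
    p_interaction: float
    contrasts: pd.DataFrame = field(repr=False)  # name, raw_p, adj_p
    method: str = "litter_permutation"
    n_perm: int = DEFAULT_N_PERM


_PAIRWISE = (
    ("WT water vs WT SC", dict(genotype="WT"), "treatment"),
    ("P0 water vs P0 SC", dict(genotype="P0"), "treatment"),
    ("WT vs P0 (water)", dict(treatment="water"), "genotype"),
    ("WT vs P0 (SC)", dict(treatment="SC"), "genotype"),
)


def compare_groups(
    fetuses: Iterable[FetusRecord] | pd.DataFrame,
    endpoint: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    method: str = "litter_permutation",
) -> GroupComparison:
    """Main effects, interaction, and Šidák-adjusted pairwise contrasts for
    one endpoint.  ``method="delegated_mixed_model"`` instead fits a linear
    mixed model with a random litter intercept (statsmodels MixedLM) for its
    main-effect and interaction p-values; contrasts remain permutation-based.
    """
    df = (
        fetuses
        if isinstance(fetuses, pd.DataFrame)
        else fetuses_to_frame(fetuses)
    )
    summaries = litter_summaries(df, endpoint)
    cells = cell_stats(summaries)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = ss.generate_state(3 + len(_PAIRWISE))

    if method == "litter_permutation":
        p_gen = permutation_test(
            summaries, "genotype", n_perm, int(seeds[0])
        ).p
        p_trt = permutation_test(
            summaries, "treatment", n_perm, int(seeds[1])
        ).p
        p_int = interaction_permutation_test(summaries, n_perm, int(seeds[2])).p
    elif method == "delegated_mixed_model":
        p_gen, p_trt, p_int = _mixed_model_pvalues(df, endpoint)
    else:
        raise ValueError(f"unknown method {method!r}")

    raw_ps, names = [], []
    for i, (name, fixed, factor) in enumerate(_PAIRWISE):
        sub = summaries
        for col, val in fixed.items():
            sub = sub[sub[col] == val]
        try:
            raw_ps.append(
                permutation_test(sub, factor, n_perm, int(seeds[3 + i])).p
            )
            names.append(name)
        except ValueError as exc:
            logger.warning("contrast %s skipped: %s", name, exc)
    adj = sequential_sidak(raw_ps) if raw_ps else np.array([])
    contrasts = pd.DataFrame({"contrast": names, "raw_p": raw_ps, "adj_p": adj})
    logger.info(
        "compare_groups[%s]: p_genotype=%.4g p_treatment=%.4g p_interaction=%.4g",
        endpoint, p_gen, p_trt, p_int,
    )
    return GroupComparison(
        endpoint=endpoint,
        cells=cells,
        p_genotype=float(p_gen),
        p_treatment=float(p_trt),
        p_interaction=float(p_int),
        contrasts=contrasts,
        method=method,
        n_perm=n_perm,
    )


def _mixed_model_pvalues(
    df: pd.DataFrame, endpoint: str
) -> tuple[float, float, float]:
    # comparison mode only; Wald z tests on the fixed effects
    import statsmodels.formula.api as smf

    data = df.rename(columns={endpoint: "y"})[
        ["y", "genotype", "treatment", "litter_id"]
    ].dropna()
    model = smf.mixedlm(
        "y ~ C(genotype) * C(treatment)", data, groups=data["litter_id"]
    )
    fit = model.fit(reml=True)
    pv = fit.pvalues
    def _grab(key):
        hits = [v for k, v in pv.items() if key in k]
        return float(hits[0]) if hits else np.nan
    return (
        _grab("C(genotype)[T."),
        _grab("C(treatment)[T."),
        _grab(":"),
    )
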