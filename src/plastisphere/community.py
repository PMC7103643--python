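"""Alpha diversity of biofilm communities and its link to bead properties.

Works on an OTU count table (samples x OTUs) with sample metadata
(polymer, treatment, replicate) and taxonomy strings.  Provides

* rarefaction to a common depth (repeated subsampling without
  replacement, indices averaged over permutations),
* the four alpha-diversity estimators used for plastisphere biofilms:
  Shannon-Wiener H (nats), Fisher's alpha, Chao1 (bias-corrected by
  default) and ACE,
* factorial ANOVA with Tukey HSD comparisons across polymers, and
* a Spearman screen pairing each sample's diversity with its polymer's
  mean physicochemical property value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .resampling import spearman

__all__ = [
    "OtuTable",
    "DiversityProfile",
    "shannon",
    "fisher_alpha",
    "chao1",
    "ace",
    "rarefy",
    "diversity_profile",
    "anova_tukey",
    "diversity_property_screen",
]

DIVERSITY_INDICES = ("shannon", "fisher_alpha", "chao1", "ace")


@dataclass
class OtuTable:
    """Integer OTU counts with sample metadata and taxonomy.

    ``counts``: DataFrame, rows = samples, columns = OTUs.
    ``metadata``: DataFrame indexed like ``counts`` with at least
    ``polymer`` (and usually ``treatment``, ``replicate``).
    ``taxonomy``: Series mapping OTU id -> lineage string.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)
        if not self.counts.index.equals(self.metadata.index):
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")
            self.metadata = self.metadata.loc[self.counts.index]
        if "polymer" not in self.metadata.columns:
            raise ValueError("metadata must contain a 'polymer' column")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every analysed sample needs a positive total count")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        tax = self.taxonomy.reindex(otu_ids) if len(self.taxonomy) else self.taxonomy
        return OtuTable(self.counts[list(otu_ids)], self.metadata.copy(), tax)


@dataclass(frozen=True)
class DiversityProfile:
    """Per-sample alpha diversity at a stated rarefaction depth."""

    values: pd.DataFrame  # rows = samples, columns = DIVERSITY_INDICES
    depth: int
    n_perm: int
    seed: Optional[int]


def shannon(counts: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def fisher_alpha(S: int, N: int, tol: float = 1e-12) -> float:
    """Fisher's alpha: the unique a > 0 with S = a * ln(1 + N/a).

    Solved with a bracketed root finder to a residual in S below 1e-8.
    Requires 0 < S < N (S = N has no finite solution).
    """
    if not 0 < S < N:
        raise ValueError("need 0 < S < N for a finite Fisher's alpha")

    def f(a: float) -> float:
        return a * np.log1p(N / a) - S

    lo, hi = 1e-10, 1e10
    alpha = float(optimize.brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))
    if abs(f(alpha)) > 1e-8:
        raise RuntimeError("Fisher's alpha root finder failed to converge")
    return alpha


def chao1(counts: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness estimator from singleton/doubleton counts.

    Bias-corrected (default): S_obs + F1 (F1 - 1) / (2 (F2 + 1)).
    Classic: S_obs + F1^2 / (2 F2), falling back to the bias-corrected
    form when F2 = 0.  Never below observed richness.
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("sample has no reads")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def ace(counts: Sequence[float], rare_threshold: int = 10) -> float:
    """Abundance-based Coverage Estimator.

    OTUs are split at abundance <= ``rare_threshold``.  With
    C_ACE = 1 - F1/N_rare and the rare-taxon coefficient of variation
    gamma^2, the estimate is S_abund + S_rare/C_ACE + F1 gamma^2/C_ACE.
    If every rare read is a singleton (C_ACE = 0) the estimator is
    undefined and Chao1 is returned with a warning.
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("sample has no reads")
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    s_abund = int((c > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "ACE undefined (all rare reads are singletons); falling back to Chao1",
            stacklevel=2,
        )
        return chao1(c)
    fi = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
    i = np.arange(1, rare_threshold + 1)
    if n_rare > 1:
        gamma2 = max(
            0.0,
            s_rare * float((i * (i - 1) * fi).sum()) / (c_ace * n_rare * (n_rare - 1))
            - 1.0,
        )
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + f1 * gamma2 / c_ace


def _indices_for_sample(counts: np.ndarray) -> Dict[str, float]:
    s = int((counts > 0).sum())
    n = int(counts.sum())
    out = {
        "richness": float(s),
        "shannon": shannon(counts),
        "chao1": chao1(counts),
        "ace": ace(counts),
    }
    out["fisher_alpha"] = fisher_alpha(s, n) if 0 < s < n else float("nan")
    return out


def rarefy(
    counts: pd.DataFrame,
    depth: int,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Alpha diversity averaged over rarefaction permutations.

    For each permutation every sample's reads are subsampled without
    replacement to ``depth`` (multivariate hypergeometric draw) and the
    four indices computed; the per-sample permutation means are
    returned (rows = samples, columns = indices).
    """
    row_sums = counts.sum(axis=1)
    low = row_sums[row_sums < depth]
    if len(low):
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total count of sample(s) "
            f"{list(low.index)[:5]}"
        )
    rng = np.random.default_rng(seed)
    columns = ("richness",) + DIVERSITY_INDICES
    acc = {sid: {k: 0.0 for k in columns} for sid in counts.index}
    values = counts.values
    for _ in range(n_perm):
        for row, sid in enumerate(counts.index):
            sub = rng.multivariate_hypergeometric(values[row], depth)
            for k, v in _indices_for_sample(sub).items():
                acc[sid][k] += v
    out = pd.DataFrame(acc).T / n_perm
    out.index.name = counts.index.name
    return out[list(columns)]


def diversity_profile(
    table: OtuTable,
    depth: Optional[int] = None,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> DiversityProfile:
    """Rarefied :class:`DiversityProfile` for every sample in the table.

    ``depth=None`` uses the minimum row sum among the analysed samples
    (rarefaction "at the treatment level").
    """
    if depth is None:
        depth = int(table.counts.sum(axis=1).min())
    values = rarefy(table.counts, depth=depth, n_perm=n_perm, seed=seed)
    return DiversityProfile(values=values, depth=depth, n_perm=n_perm, seed=seed)


def anova_tukey(
    data: pd.DataFrame,
    value_col: str = "value",
    polymer_col: str = "polymer",
    index_col: Optional[str] = "index",
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA across polymers with Tukey HSD pairwise comparisons.

    With ``index_col`` given, fits the factorial model
    ``value ~ polymer * index`` and reports SS/DF/MS/F/p for both main
    effects, their interaction, and the residual; Tukey HSD comparisons
    between polymers are then run separately per diversity index.  With
    ``index_col=None`` a one-way ANOVA on polymer is fitted.

    Returns ``(anova_table, tukey_table)``.
    """
    df = data.copy()
    for col in [value_col, polymer_col] + ([index_col] if index_col else []):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    group_cols = [polymer_col] + ([index_col] if index_col else [])
    sizes = df.groupby(group_cols, observed=True)[value_col].size()
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 replicates")
    if df[value_col].var(ddof=0) == 0:
        anova = pd.DataFrame(
            {"SS": [0.0], "DF": [len(df) - 1], "MS": [0.0],
             "F": [np.nan], "p": [np.nan]},
            index=["constant data"],
        )
        pairs = []
        for idx_val, sub in (
            df.groupby(index_col, observed=True) if index_col else [("all", df)]
        ):
            groups = sorted(sub[polymer_col].unique())
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    pairs.append(
                        {"index": idx_val, "group1": g1, "group2": g2,
                         "mean_diff": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                         "p_adj": np.nan, "significant": False}
                    )
        return anova, pd.DataFrame(pairs)

    if index_col:
        model = ols(
            f"Q('{value_col}') ~ C(Q('{polymer_col}')) * C(Q('{index_col}'))", df
        ).fit()
        raw = anova_lm(model, typ=2)
        rename = {}
        for row in raw.index:
            if ":" in row:
                rename[row] = "interaction"
            elif polymer_col in row:
                rename[row] = "polymer"
            elif index_col in row:
                rename[row] = "diversity index"
            else:
                rename[row] = row.lower()
        raw = raw.rename(index=rename)
    else:
        model = ols(f"Q('{value_col}') ~ C(Q('{polymer_col}'))", df).fit()
        raw = anova_lm(model, typ=2)
        raw = raw.rename(index=lambda r: "polymer" if polymer_col in r else r.lower())
    anova = pd.DataFrame(
        {
            "SS": raw["sum_sq"],
            "DF": raw["df"].astype(int),
            "MS": raw["sum_sq"] / raw["df"],
            "F": raw["F"],
            "p": raw["PR(>F)"],
        }
    )

    pairs = []
    grouped = df.groupby(index_col, observed=True) if index_col else [("all", df)]
    for idx_val, sub in grouped:
        tk = pairwise_tukeyhsd(sub[value_col], sub[polymer_col], alpha=alpha)
        groups_sorted = np.unique(sub[polymer_col].to_numpy())
        pair_labels = [
            (groups_sorted[i], groups_sorted[j])
            for i in range(len(groups_sorted))
            for j in range(i + 1, len(groups_sorted))
        ]
        for k, (g1, g2) in enumerate(pair_labels):
            pairs.append(
                {
                    "index": idx_val,
                    "group1": g1,
                    "group2": g2,
                    "mean_diff": float(tk.meandiffs[k]),
                    "ci_low": float(tk.confint[k, 0]),
                    "ci_high": float(tk.confint[k, 1]),
                    "p_adj": float(tk.pvalues[k]),
                    "significant": bool(tk.reject[k]),
                }
            )
    return anova, pd.DataFrame(pairs)


def diversity_property_screen(
    diversity: pd.DataFrame,
    polymers: pd.Series,
    properties: pd.DataFrame,
    mode: str = "samples",
) -> pd.DataFrame:
    """Spearman screen between diversity indices and bead properties.

    ``diversity``: per-sample index values (rows = samples, columns =
    indices).  ``polymers``: sample -> polymer label.  ``properties``:
    per-polymer mean property values (rows = polymers, columns =
    properties).  In ``mode="samples"`` each sample is paired with its
    polymer's mean property (tied property ranks within a polymer); in
    ``mode="polymer_means"`` indices are first averaged per polymer.

    Returns a long table: index, property, rho, p, n.
    """
    missing = set(polymers.unique()) - set(properties.index)
    if missing:
        raise ValueError(f"properties missing for polymers: {sorted(missing)}")
    if mode == "polymer_means":
        div = diversity.groupby(polymers).mean()
        poly_of_row = pd.Series(div.index, index=div.index)
    elif mode == "samples":
        div = diversity
        poly_of_row = polymers
    else:
        raise ValueError("mode must be 'samples' or 'polymer_means'")
    rows = []
    for index_name in div.columns:
        for prop_name in properties.columns:
            x = div[index_name].to_numpy(dtype=float)
            y = properties.loc[poly_of_row.loc[div.index], prop_name].to_numpy(
                dtype=float
            )
            rec = {"index": index_name, "property": prop_name, "n": len(x)}
            try:
                res = spearman(x, y)
                rec["rho"], rec["p"] = res.r, res.p
            except ValueError:
                rec["rho"], rec["p"] = np.nan, np.nan
                rec["constant_input"] = True
            rows.append(rec)
    return pd.DataFrame(rows)
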