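"""Parametric gene-set enrichment (PAGE) on per-contrast D statistics.

A GO biological-process membership matrix is intersected with the universe
of genes that have D statistics, categories below a minimum size are
dropped, and each surviving category is tested per contrast with the PAGE
z statistic

    z = (Sm - mu) * sqrt(m) / sigma

where ``Sm`` is the category's mean D, ``mu`` and ``sigma`` the mean and
(population) standard deviation of the universe's D values, and ``m`` the
category size.  Two-sided normal p values are Benjamini-Hochberg adjusted
within each contrast's family of categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from whorlstat.io import GOAnnotationTable


@dataclass
class GOMatrix:
    """Filtered category membership over a gene universe."""

    categories: pd.DataFrame  # go_id, description, members (tuple of gene ids)
    universe: tuple[str, ...]
    min_size: int
    dropped: pd.DataFrame | None = None  # go_id, size_on_array

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_genes(self) -> int:
        used = set()
        for m in self.categories["members"]:
            used.update(m)
        return len(used)


def build_go_matrix(
    annotations: GOAnnotationTable, universe, min_size: int = 10
) -> GOMatrix:
    """Intersect annotations with the universe, then drop categories with
    fewer than ``min_size`` members (size counted after intersection; a
    category with exactly ``min_size`` members is kept)."""
    universe = tuple(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    uset = set(universe)
    rec = annotations.records
    rows, dropped = [], []
    if len(rec):
        for go_id, grp in rec.groupby("go_id", sort=True):
            members = tuple(g for g in grp["gene_id"] if g in uset)
            desc = grp["go_description"].iloc[0]
            if len(members) >= min_size:
                rows.append((go_id, desc, members))
            else:
                dropped.append((go_id, len(members)))
    categories = pd.DataFrame(rows, columns=["go_id", "description", "members"])
    return GOMatrix(
        categories=categories,
        universe=universe,
        min_size=min_size,
        dropped=pd.DataFrame(dropped, columns=["go_id", "size_on_array"]),
    )


def page_z(d_universe, member_index) -> tuple[int, float, float, float, float, float]:
    """PAGE statistic for one category.

    Parameters
    ----------
    d_universe : array of D statistics over the universe genes
    member_index : integer indices (or boolean mask) of the category's
        members within the universe

    Returns
    -------
    (m, Sm, mu, sigma, z, p) with sigma the population (denominator N)
    standard deviation of the universe and p the two-sided normal tail.
    """
    d = np.asarray(d_universe, dtype=float)
    members = d[np.asarray(member_index)]
    m = int(members.size)
    if m < 1:
        raise ValueError("category must have at least one member")
    mu = float(d.mean())
    sigma = float(d.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate universe: all D statistics identical")
    Sm = float(members.mean())
    z = (Sm - mu) * np.sqrt(m) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return m, Sm, mu, sigma, float(z), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    d_table: pd.DataFrame,
    go_matrix: GOMatrix,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """PAGE enrichment of every category under every contrast.

    ``d_table`` is genes x contrasts.  BH adjustment is applied within each
    contrast's family of categories; the result is sorted by contrast then
    adjusted p.
    """
    missing = [g for g in go_matrix.universe if g not in d_table.index]
    if missing:
        raise ValueError(
            f"universe genes missing from the D table: {missing[:5]}"
        )
    uni = list(go_matrix.universe)
    pos = {g: i for i, g in enumerate(uni)}
    member_idx = [
        np.array([pos[g] for g in members], dtype=int)
        for members in go_matrix.categories["members"]
    ]
    frames = []
    for contrast in d_table.columns:
        d = d_table.loc[uni, contrast].to_numpy(float)
        rows = []
        for (go_id, desc), idx in zip(
            go_matrix.categories[["go_id", "description"]].itertuples(
                index=False
            ),
            member_idx,
        ):
            m, Sm, mu, sigma, z, p = page_z(d, idx)
            rows.append((contrast, go_id, desc, m, Sm, mu, sigma, z, p))
        if not rows:
            continue
        frame = pd.DataFrame(
            rows,
            columns=[
                "contrast", "go_id", "description", "m", "Sm", "mu",
                "sigma", "z", "p",
            ],
        )
        frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
        frame["direction"] = np.where(frame["Sm"] > frame["mu"], "up", "down")
        frame["significant"] = frame["p_adj"] < alpha
        frames.append(frame.sort_values("p_adj", kind="stable"))
    if not frames:
        return pd.DataFrame(
            columns=[
                "contrast", "go_id", "description", "m", "Sm", "mu", "sigma",
                "z", "p", "p_adj", "direction", "significant",
            ]
        )
    return pd.concat(frames, ignore_index=True)


class PageEnrichment(BaseEstimator):
    """PAGE gene-set enrichment as an estimator.

    Parameters
    ----------
    min_size : int, default 10
        Minimum category size after intersection with the universe.
    alpha : float, default 0.01
        Significance cutoff on the BH-adjusted p value.

    Attributes
    ----------
    go_matrix_ : GOMatrix after filtering
    results_ : DataFrame of per-(contrast, category) statistics
    """

    def __init__(self, min_size: int = 10, alpha: float = 0.01):
        self.min_size = min_size
        self.alpha = alpha

    def fit(self, d_table: pd.DataFrame, annotations: GOAnnotationTable,
            universe=None):
        """Filter the annotation matrix and test every (category, contrast).

        ``universe`` defaults to the annotated genes that have D
        statistics (genes with neither are excluded from the reference
        distribution).
        """
        if universe is None:
            annotated = set(annotations.records["gene_id"])
            universe = [g for g in d_table.index if g in annotated]
        self.go_matrix_ = build_go_matrix(
            annotations, universe, min_size=self.min_size
        )
        self.results_ = enrich(d_table, self.go_matrix_, alpha=self.alpha)
        return self
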