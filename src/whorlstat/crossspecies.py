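"""Homolog pairing and cross-species correlation of expression statistics.

Putative homologs between two species are derived from two directional
alignment hit tables (BLAST tabular) as reciprocal best hits: after
applying each direction's inclusive E-value threshold, a pair (a, b) is
kept when b is a's best hit and a is b's best hit.  D statistics of the
paired genes are then compared across species with Spearman rank
correlations, and within one species across whorls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from whorlstat.io import AlignmentHits


@dataclass
class HomologPairs:
    """One-to-one reciprocal pairs with the E-values supporting them."""

    pairs: pd.DataFrame  # gene_a, gene_b, e_ab, e_ba
    thresholds: tuple[float, float]
    mode: str = "best-hit"

    def __post_init__(self) -> None:
        if self.mode == "best-hit" and len(self.pairs):
            if self.pairs["gene_a"].duplicated().any():
                raise ValueError("a gene_a appears in more than one pair")
            if self.pairs["gene_b"].duplicated().any():
                raise ValueError("a gene_b appears in more than one pair")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CorrelationResult:
    """Spearman correlation matrix with p values and pair counts."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flag_threshold: float = 0.001

    def significant(self) -> pd.DataFrame:
        return self.p < self.flag_threshold


def _best_hits(hits: AlignmentHits) -> pd.Series:
    """Best in-threshold hit per query: lowest E-value, ties broken by
    highest bit score then lexicographically smallest subject id."""
    rec = hits.within_threshold()
    if not len(rec):
        return pd.Series(dtype=object)
    rec = rec.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    best = rec.drop_duplicates(subset="query_id", keep="first")
    return best.set_index("query_id")["subject_id"]


def reciprocal_pairs(
    hits_ab: AlignmentHits, hits_ba: AlignmentHits, mode: str = "best-hit"
) -> HomologPairs:
    """Derive homolog pairs from the two directional hit tables.

    ``best-hit`` (default) keeps (a, b) iff each is the other's best hit,
    guaranteeing one-to-one pairs.  ``any-intersection`` keeps every (a, b)
    with an in-threshold hit in both directions (not one-to-one).
    """
    thresholds = (hits_ab.e_threshold, hits_ba.e_threshold)
    if mode == "any-intersection":
        ab = hits_ab.within_threshold()[["query_id", "subject_id", "e_value"]]
        ba = hits_ba.within_threshold()[["query_id", "subject_id", "e_value"]]
        ab = ab.rename(
            columns={"query_id": "gene_a", "subject_id": "gene_b", "e_value": "e_ab"}
        ).drop_duplicates(["gene_a", "gene_b"])
        ba = ba.rename(
            columns={"query_id": "gene_b", "subject_id": "gene_a", "e_value": "e_ba"}
        ).drop_duplicates(["gene_a", "gene_b"])
        pairs = ab.merge(ba, on=["gene_a", "gene_b"], how="inner")
        pairs = pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        return HomologPairs(pairs=pairs, thresholds=thresholds, mode=mode)
    if mode != "best-hit":
        raise ValueError(f"unknown mode {mode!r}")
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    rows = []
    ab_e = hits_ab.within_threshold().set_index(["query_id", "subject_id"])[
        "e_value"
    ]
    ba_e = hits_ba.within_threshold().set_index(["query_id", "subject_id"])[
        "e_value"
    ]
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            rows.append(
                (a, b, float(ab_e.loc[(a, b)].min()), float(ba_e.loc[(b, a)].min()))
            )
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "e_ab", "e_ba"])
    pairs = pairs.sort_values("gene_a").reset_index(drop=True)
    return HomologPairs(pairs=pairs, thresholds=thresholds, mode=mode)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties; p from the t approximation
    with n-2 df.  Returns (nan, nan) when either vector is constant."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_d(
    dstats_a: pd.DataFrame,
    dstats_b: pd.DataFrame,
    pairs: HomologPairs,
    contrasts_a=None,
    contrasts_b=None,
    flag_p: float = 0.001,
) -> CorrelationResult:
    """Cross-species Spearman correlation of D statistics over homolog
    pairs, for every (contrast_b, contrast_a) combination.

    Pairs whose genes lack a D statistic in either species are dropped;
    the pair count actually used is reported per cell, and cells with
    fewer than 3 usable pairs are left missing.
    """
    if contrasts_a is None:
        contrasts_a = list(dstats_a.columns)
    if contrasts_b is None:
        contrasts_b = list(dstats_b.columns)
    usable = pairs.pairs[
        pairs.pairs["gene_a"].isin(dstats_a.index)
        & pairs.pairs["gene_b"].isin(dstats_b.index)
    ]
    if len(usable) < 3:
        raise ValueError(
            f"need >=3 pairs with D statistics in both species, got {len(usable)}"
        )
    A = dstats_a.loc[usable["gene_a"], contrasts_a].to_numpy(float)
    B = dstats_b.loc[usable["gene_b"], contrasts_b].to_numpy(float)
    rho = pd.DataFrame(index=contrasts_b, columns=contrasts_a, dtype=float)
    p = pd.DataFrame(index=contrasts_b, columns=contrasts_a, dtype=float)
    n = pd.DataFrame(
        len(usable), index=contrasts_b, columns=contrasts_a, dtype=int
    )
    for i, cb in enumerate(contrasts_b):
        for j, ca in enumerate(contrasts_a):
            r, pv = _spearman(A[:, j], B[:, i])
            rho.loc[cb, ca] = r
            p.loc[cb, ca] = pv
    return CorrelationResult(rho=rho, p=p, n=n, flag_threshold=flag_p)


def whorl_correlations(
    per_whorl: pd.DataFrame,
    flag_p: float = 0.001,
) -> CorrelationResult:
    """Spearman correlation between whorls of a per-whorl gene statistic.

    ``per_whorl`` is genes x whorls -- either the whorl-specific contrast
    D statistics (columns = the singleton contrasts, the default choice)
    or gene-centered mean log2 expression per whorl.  Cells where a
    whorl's statistic is constant are reported missing.
    """
    if len(per_whorl) < 3:
        raise ValueError("need >=3 genes")
    whorls = list(per_whorl.columns)
    X = per_whorl.to_numpy(float)
    rho = pd.DataFrame(np.nan, index=whorls, columns=whorls, dtype=float)
    p = pd.DataFrame(np.nan, index=whorls, columns=whorls, dtype=float)
    n = pd.DataFrame(len(per_whorl), index=whorls, columns=whorls, dtype=int)
    for i, wi in enumerate(whorls):
        rho.loc[wi, wi] = 1.0
        p.loc[wi, wi] = 0.0
        for j in range(i + 1, len(whorls)):
            wj = whorls[j]
            r, pv = _spearman(X[:, i], X[:, j])
            rho.loc[wi, wj] = rho.loc[wj, wi] = r
            p.loc[wi, wj] = p.loc[wj, wi] = pv
    return CorrelationResult(rho=rho, p=p, n=n, flag_threshold=flag_p)


def centered_whorl_means(expr_values: pd.DataFrame, design) -> pd.DataFrame:
    """Gene-centered mean log2 expression per whorl (the alternative
    per-whorl statistic for :func:`whorl_correlations`)."""
    tissue_of = design.tissue_of()
    cols = {}
    for tissue in design.tissue_set:
        arrays = [a for a in expr_values.columns if tissue_of[a] == tissue]
        cols[tissue] = expr_values[arrays].mean(axis=1)
    out = pd.DataFrame(cols)
    return out.sub(out.mean(axis=1), axis=0)
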