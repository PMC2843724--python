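"""SAM-style contrast analysis for whorl x replicate-block designs.

For each gene and each whorl-group contrast (one group of whorls against
the remaining whorls) the engine computes a paired group-difference
coefficient across population blocks, its standard error, and a
standardized D statistic

    D = coefficient / (se + s0)

where the fudge constant ``s0`` is the median standard error over all
genes for that contrast.  Significance is assessed SAM-style: D statistics
are recomputed on label-permuted data, ranked D values are averaged over
permutations, and a gene is called when its observed ranked D departs from
the permutation expectation by more than a delta threshold.  The false
discovery rate is the median permuted exceedance count beyond the call
cutoffs divided by the number of calls.  Finally every gene is assigned
the contrast where its absolute D is maximal ("specific expression").

The population random effect of the underlying per-gene linear model is
handled by within-block differencing: with one array per tissue x block,
the block-wise group difference is free of any additive block effect, and
averaging the block differences is the exact generalized-least-squares
estimate under a block-shift model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from whorlstat.io import StudyDesign, canonical_tissue_set
from whorlstat.preprocess import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    """One whorl-group contrast: ``group`` against every other whorl."""

    id: int
    group: frozenset[str]
    complement: frozenset[str]
    name: str

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("contrast group must be nonempty")
        if self.group & self.complement:
            raise ValueError("contrast group and complement overlap")


_FIVE_WHORL_GROUPS = {
    1: ("SEP",),
    2: ("PET",),
    3: ("STA",),
    4: ("STD",),
    5: ("CAR",),
    6: ("SEP", "PET"),
    7: ("SEP", "PET", "STA"),
    8: ("PET", "STA"),
    9: ("PET", "STA", "STD"),
    10: ("STA", "STD"),
    11: ("STA", "STD", "CAR"),
    12: ("STA", "CAR"),
}

_FIVE_WHORL_NAMES = {
    6: "A = SEP+PET",
    7: "B+SEP = SEP+PET+STA",
    8: "B = PET+STA",
    9: "B+STD = PET+STA+STD",
    10: "STA+STD",
    11: "C+STD = STA+STD+CAR",
    12: "C = STA+CAR",
}

_FOUR_WHORL_GROUPS = {
    1: ("SEP",),
    2: ("PET",),
    3: ("STA",),
    4: ("CAR",),
    5: ("SEP", "PET"),
    6: ("PET", "STA"),
    7: ("STA", "CAR"),
}

_FOUR_WHORL_NAMES = {5: "A = SEP+PET", 6: "B = PET+STA", 7: "C = STA+CAR"}


def make_contrasts(tissue_set) -> list[Contrast]:
    """The canonical contrast set for a 5- or 4-whorl design.

    Five whorls give 12 contrasts: each whorl against the rest (1-5), the
    A/B/C identity domains (6 = SEP+PET, 8 = PET+STA, 12 = STA+CAR) and
    the staminodium-motivated groupings (7, 9, 10, 11).  Four whorls give
    the four singletons plus A, B, C (7 contrasts).
    """
    tissue_set = canonical_tissue_set(tissue_set)
    if len(tissue_set) == 5:
        groups, names = _FIVE_WHORL_GROUPS, _FIVE_WHORL_NAMES
    elif len(tissue_set) == 4:
        groups, names = _FOUR_WHORL_GROUPS, _FOUR_WHORL_NAMES
    else:
        raise ValueError(
            f"contrasts are defined for 4 or 5 whorls, got {len(tissue_set)}"
        )
    out = []
    full = set(tissue_set)
    for cid, grp in groups.items():
        g = frozenset(grp)
        out.append(
            Contrast(
                id=cid,
                group=g,
                complement=frozenset(full - g),
                name=names.get(cid, "+".join(grp)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# core fitting


def _block_differences(
    X: np.ndarray,
    tissues: np.ndarray,
    populations: np.ndarray,
    group: frozenset,
    pops: np.ndarray,
) -> np.ndarray:
    """Per-population group-minus-complement mean differences.

    X is genes x arrays.  Returns genes x n_populations with NaN columns
    for blocks where the group or complement is empty under the given
    labelling (possible only for permuted labels).
    """
    in_group = np.isin(tissues, list(group))
    W = np.zeros((X.shape[1], len(pops)))
    for j, p in enumerate(pops):
        in_pop = populations == p
        g = in_group & in_pop
        c = ~in_group & in_pop
        ng, nc = g.sum(), c.sum()
        if ng == 0 or nc == 0:
            W[:, j] = np.nan
            continue
        W[g, j] = 1.0 / ng
        W[c, j] = -1.0 / nc
    return X @ W


def _fit_from_diffs(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Coefficient and standard error from block differences.

    coefficient = mean of block differences; se = sample sd / sqrt(P) over
    the defined blocks.  Returns (coef, se, n_defined_blocks).
    """
    defined = ~np.isnan(D[0])
    P = int(defined.sum())
    if P < 2:
        raise ValueError(
            "contrast needs >=2 population blocks with both group and "
            f"complement arrays; got {P}"
        )
    Dd = D[:, defined]
    coef = Dd.mean(axis=1)
    se = Dd.std(axis=1, ddof=1) / np.sqrt(P)
    return coef, se, P


def fit_contrast(
    expr: ExpressionMatrix, contrast: Contrast
) -> pd.DataFrame:
    """Per-gene coefficient and standard error for one contrast.

    The coefficient is the mean over population blocks of the group-mean
    minus complement-mean difference; the standard error is the sample
    standard deviation of the block differences divided by sqrt(P).
    """
    if expr.design is None:
        raise ValueError("ExpressionMatrix carries no design")
    design = expr.design
    tissues = np.array([design.tissue_of()[a] for a in expr.array_ids])
    populations = np.array([design.population_of()[a] for a in expr.array_ids])
    pops = np.array(sorted(set(populations)))
    X = expr.values.to_numpy(float)
    D = _block_differences(X, tissues, populations, contrast.group, pops)
    if np.isnan(D).any():
        bad = pops[np.isnan(D[0])]
        raise ValueError(
            f"contrast {contrast.id} has an empty group or complement in "
            f"population block(s) {list(bad)}"
        )
    coef, se, _ = _fit_from_diffs(D)
    return pd.DataFrame(
        {"coefficient": coef, "se": se}, index=expr.gene_ids
    )


def d_statistics(
    coefs, ses, s0: float | None = None, s0_floor: float = 1e-9
) -> tuple[np.ndarray, float]:
    """D statistics with the median-standard-error fudge constant.

    ``s0`` defaults to the median of the standard errors over genes,
    floored at ``s0_floor`` to keep zero-variance toys finite.  Returns
    (d, s0).
    """
    coefs = np.asarray(coefs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if coefs.size == 0:
        raise ValueError("need at least one gene")
    if s0 is None:
        s0 = float(np.median(ses))
    s0 = max(float(s0), s0_floor)
    return coefs / (ses + s0), s0


def permute_labels(
    design: StudyDesign,
    n_perm: int = 99,
    seed: int | None = 0,
    within_blocks: bool = False,
) -> list[np.ndarray]:
    """Random relabellings of the arrays' tissue assignments.

    Each permutation is a uniform shuffle of the tissue labels over all
    arrays (population labels stay attached to their arrays).  With
    ``within_blocks`` the shuffle is restricted to each population block.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = design.entries["tissue"].to_numpy()
    populations = design.entries["population"].to_numpy()
    out = []
    for _ in range(n_perm):
        if within_blocks:
            perm = tissues.copy()
            for p in np.unique(populations):
                idx = np.flatnonzero(populations == p)
                perm[idx] = perm[rng.permutation(idx)]
        else:
            perm = tissues[rng.permutation(len(tissues))]
        out.append(perm)
    return out


def expected_ranked_d(perm_d) -> np.ndarray:
    """Rank-wise mean of the permuted D statistics.

    perm_d: (n_perm, n_genes).  Result is the nondecreasing vector whose
    i-th entry is the mean over permutations of the i-th order statistic.
    """
    perm_d = np.asarray(perm_d, dtype=float)
    if perm_d.ndim == 1:
        perm_d = perm_d[None, :]
    return np.sort(perm_d, axis=1).mean(axis=0)


@dataclass
class SignificanceCall:
    """SAM calling result for one contrast."""

    contrast_id: int
    delta: float
    gene_order: np.ndarray  # gene indices sorted by observed d, ascending
    observed_sorted: np.ndarray
    expected: np.ndarray
    up_genes: np.ndarray  # indices into the original gene order
    down_genes: np.ndarray
    cut_up: float
    cut_low: float
    fdr: float

    @property
    def n_called(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def call_significant(
    observed_d,
    expected,
    perm_d,
    delta: float = 4.0,
    contrast_id: int = 0,
) -> SignificanceCall:
    """SAM delta-threshold calling with a permutation FDR.

    A gene at rank i (of the ascending observed D) is called when
    ``observed(i) - expected(i)`` exceeds ``delta`` (up) or falls below
    ``-delta`` (down).  The FDR estimate is the median over permutations
    of the number of permuted D values beyond the call cutoffs, divided by
    the number of called genes (0 when nothing is called, capped at 1).
    """
    observed_d = np.asarray(observed_d, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed_d.shape != expected.shape:
        raise ValueError("observed and expected must have the same length")
    perm_d = np.asarray(perm_d, dtype=float)
    if perm_d.ndim == 1:
        perm_d = perm_d[None, :]
    order = np.argsort(observed_d, kind="stable")
    obs_sorted = observed_d[order]
    diff = obs_sorted - expected
    up_mask = diff > delta
    down_mask = diff < -delta
    up_genes = order[up_mask]
    down_genes = order[down_mask]
    cut_up = obs_sorted[up_mask].min() if up_mask.any() else np.inf
    cut_low = obs_sorted[down_mask].max() if down_mask.any() else -np.inf
    n_called = up_mask.sum() + down_mask.sum()
    if n_called == 0:
        fdr = 0.0
    else:
        exceed = ((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1)
        fdr = min(1.0, float(np.median(exceed)) / n_called)
    return SignificanceCall(
        contrast_id=contrast_id,
        delta=float(delta),
        gene_order=order,
        observed_sorted=obs_sorted,
        expected=expected,
        up_genes=up_genes,
        down_genes=down_genes,
        cut_up=float(cut_up),
        cut_low=float(cut_low),
        fdr=fdr,
    )


def assign_specific(d_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to the contrast where |D| is maximal.

    ``d_table`` is genes x contrasts with columns ordered (and labelled)
    by contrast id.  Ties go to the lowest contrast id; the direction is
    the sign of D at the winning contrast.
    """
    vals = d_table.to_numpy(float)
    if vals.size == 0:
        raise ValueError("empty D-statistic table")
    win = np.argmax(np.abs(vals), axis=1)  # first max -> lowest contrast id
    d_at = vals[np.arange(len(vals)), win]
    return pd.DataFrame(
        {
            "specific_contrast": np.asarray(d_table.columns)[win],
            "direction": np.sign(d_at).astype(int),
            "d": d_at,
        },
        index=d_table.index,
    )


# ---------------------------------------------------------------------------
# estimator


class SAMContrastAnalyzer(BaseEstimator):
    """Whole-study contrast analysis as a scikit-learn style estimator.

    Parameters
    ----------
    delta : float, default 4.0
        SAM delta threshold.
    n_perm : int, default 99
        Number of label permutations for the null.
    seed : int, default 0
        Seed for the permutation stream.
    within_blocks : bool, default False
        Restrict label shuffling to population blocks.  Unconstrained
        shuffling can leave a block without group (or complement) arrays
        for some contrast; such blocks are dropped from that contrast's
        fit, and a permutation is redrawn if fewer than two blocks remain.
    resample : {"permute", "bootstrap"}, default "permute"
        "bootstrap" draws tissue labels with replacement instead of
        shuffling.
    s0_floor : float, default 1e-9
        Lower bound on the fudge constant.

    Attributes
    ----------
    contrasts_ : list of Contrast
    gene_ids_ : ndarray of the fitted gene identifiers
    coefficients_, se_, d_ : DataFrames, genes x contrasts
    s0_ : dict contrast id -> fudge constant
    expected_d_ : dict contrast id -> expected ranked D
    calls_ : dict contrast id -> SignificanceCall
    fdr_ : dict contrast id -> estimated FDR at delta
    specific_ : DataFrame with specific_contrast, direction, d per gene
    """

    def __init__(
        self,
        delta: float = 4.0,
        n_perm: int = 99,
        seed: int = 0,
        within_blocks: bool = False,
        resample: str = "permute",
        s0_floor: float = 1e-9,
    ):
        self.delta = delta
        self.n_perm = n_perm
        self.seed = seed
        self.within_blocks = within_blocks
        self.resample = resample
        self.s0_floor = s0_floor

    # -- helpers ---------------------------------------------------------

    def _all_contrast_stats(self, X, tissues, populations, pops, contrasts, s0s):
        """d per contrast for one labelling; None if some contrast has <2
        usable blocks."""
        ds = {}
        for c in contrasts:
            D = _block_differences(X, tissues, populations, c.group, pops)
            defined = ~np.isnan(D[0])
            if defined.sum() < 2:
                return None
            try:
                coef, se, _ = _fit_from_diffs(D)
            except ValueError:
                return None
            d, _ = d_statistics(coef, se, s0=s0s[c.id], s0_floor=self.s0_floor)
            ds[c.id] = d
        return ds

    def fit(self, X, y=None, *, populations=None, design: StudyDesign | None = None):
        """Fit on arrays x genes data.

        Either pass ``X`` as an ExpressionMatrix (design included), or as
        an (n_arrays, n_genes) matrix/DataFrame with ``y`` the tissue label
        per array and ``populations`` the block label per array.
        """
        if isinstance(X, ExpressionMatrix):
            expr = X
            if expr.design is None:
                raise ValueError("ExpressionMatrix carries no design")
            design = expr.design
            tissues = np.array([design.tissue_of()[a] for a in expr.array_ids])
            populations = np.array(
                [design.population_of()[a] for a in expr.array_ids]
            )
            gene_ids = np.asarray(expr.gene_ids)
            M = expr.values.to_numpy(float)  # genes x arrays
        else:
            if y is None or populations is None:
                raise ValueError(
                    "matrix input requires y (tissues) and populations"
                )
            if isinstance(X, pd.DataFrame):
                gene_ids = np.asarray(X.columns)
                M = X.to_numpy(float).T
            else:
                X = np.asarray(X, dtype=float)
                gene_ids = np.array([f"g{i}" for i in range(X.shape[1])])
                M = X.T
            tissues = np.asarray(y)
            populations = np.asarray(populations)
        if M.shape[1] != len(tissues):
            raise ValueError("label length does not match the number of arrays")
        pops = np.array(sorted(set(populations)))
        if len(pops) < 2:
            raise ValueError("need >=2 population blocks for a standard error")
        tissue_set = canonical_tissue_set(tissues)
        contrasts = make_contrasts(tissue_set)

        # observed fit; s0 fixed per contrast from the observed data
        coefs, ses, ds, s0s = {}, {}, {}, {}
        for c in contrasts:
            D = _block_differences(M, tissues, populations, c.group, pops)
            if np.isnan(D).any():
                raise ValueError(
                    f"contrast {c.id}: empty group or complement in a block"
                )
            coef, se, _ = _fit_from_diffs(D)
            d, s0 = d_statistics(coef, se, s0_floor=self.s0_floor)
            coefs[c.id], ses[c.id], ds[c.id], s0s[c.id] = coef, se, d, s0

        # permutation null (shared label draws across contrasts)
        rng = np.random.default_rng(self.seed)
        perm_ds: dict[int, list[np.ndarray]] = {c.id: [] for c in contrasts}
        n_done = 0
        n_attempts = 0
        max_attempts = self.n_perm * 200
        while n_done < self.n_perm:
            n_attempts += 1
            if n_attempts > max_attempts:
                raise RuntimeError(
                    "could not draw enough non-degenerate permutations; "
                    "consider within_blocks=True"
                )
            if self.resample == "bootstrap":
                perm = tissues[rng.integers(0, len(tissues), len(tissues))]
            elif self.within_blocks:
                perm = tissues.copy()
                for p in pops:
                    idx = np.flatnonzero(populations == p)
                    perm[idx] = perm[rng.permutation(idx)]
            else:
                perm = tissues[rng.permutation(len(tissues))]
            stats = self._all_contrast_stats(
                M, perm, populations, pops, contrasts, s0s
            )
            if stats is None:
                continue  # degenerate under this labelling; redraw
            for cid, d in stats.items():
                perm_ds[cid].append(d)
            n_done += 1

        cids = [c.id for c in contrasts]
        self.contrasts_ = contrasts
        self.gene_ids_ = gene_ids
        self.coefficients_ = pd.DataFrame(
            {cid: coefs[cid] for cid in cids}, index=gene_ids
        )
        self.se_ = pd.DataFrame({cid: ses[cid] for cid in cids}, index=gene_ids)
        self.d_ = pd.DataFrame({cid: ds[cid] for cid in cids}, index=gene_ids)
        self.s0_ = s0s
        self.expected_d_ = {}
        self.calls_ = {}
        self.fdr_ = {}
        for cid in cids:
            P = np.vstack(perm_ds[cid])
            expected = expected_ranked_d(P)
            call = call_significant(
                ds[cid], expected, P, delta=self.delta, contrast_id=cid
            )
            self.expected_d_[cid] = expected
            self.calls_[cid] = call
            self.fdr_[cid] = call.fdr
        self._perm_d = perm_ds
        self.specific_ = assign_specific(self.d_)
        return self

    def calls_at(self, delta: float) -> dict[int, SignificanceCall]:
        """Re-threshold the fitted permutation null at another delta."""
        out = {}
        for cid, P in self._perm_d.items():
            Pm = np.vstack(P)
            out[cid] = call_significant(
                self.d_[cid].to_numpy(),
                self.expected_d_[cid],
                Pm,
                delta=delta,
                contrast_id=cid,
            )
        return out

    def summary(self) -> pd.DataFrame:
        """Per-contrast call counts, FDR and specificity counts."""
        rows = []
        spec = self.specific_
        for c in self.contrasts_:
            call = self.calls_[c.id]
            in_c = spec["specific_contrast"] == c.id
            rows.append(
                {
                    "contrast": c.id,
                    "name": c.name,
                    "n_down": len(call.down_genes),
                    "n_up": len(call.up_genes),
                    "fdr": call.fdr,
                    "n_specific_down": int((in_c & (spec["direction"] < 0)).sum()),
                    "n_specific_up": int((in_c & (spec["direction"] > 0)).sum()),
                }
            )
        return pd.DataFrame(rows)


def sam_plot(analyzer: SAMContrastAnalyzer, contrast_id: int, ax=None):
    """Observed-vs-expected ranked-D scatter with the delta band."""
    import matplotlib.pyplot as plt

    call = analyzer.calls_[contrast_id]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(call.expected, call.observed_sorted, s=4, c="k")
    lo, hi = call.expected.min(), call.expected.max()
    ax.plot([lo, hi], [lo, hi], "r-", lw=1)
    ax.plot([lo, hi], [lo + call.delta, hi + call.delta], "r--", lw=0.8)
    ax.plot([lo, hi], [lo - call.delta, hi - call.delta], "r--", lw=0.8)
    ax.set_xlabel("expected ranked D")
    ax.set_ylabel("observed ranked D")
    ax.set_title(f"contrast {contrast_id} (delta={call.delta}, FDR={call.fdr:.3g})")
    return ax
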