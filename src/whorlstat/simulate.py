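"""Synthetic probe-level studies with planted ground truth.

The generator mirrors the analysis model: probe j of gene g on array a
(tissue t, population block p) has log2 intensity

    baseline_g + effect_g * [t in planted group of g] + affinity_j
    + block_gp + surface_a(x_j, y_j) + noise

with gene baselines, probe affinities, per-(gene, block) random effects
and per-measurement noise all Gaussian on the log2 scale, and a smooth
per-array spatial surface (sum of two low-frequency 2-D cosines with
random phase).  Raw intensities are 2**log2 so the pipeline's log step is
exercised.  Everything is a pure function of (params, seed).

Companion generators produce GO annotation tables with planted enriched
categories and directional alignment-hit tables with planted reciprocal
pairs, each returning its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from whorlstat.io import (
    AlignmentHits,
    GOAnnotationTable,
    ProbeIntensityTable,
    StudyDesign,
    WHORL_ORDER,
)
from whorlstat.differential import make_contrasts


@dataclass
class SimulationParams:
    """Study-generator settings.

    All scale parameters are in log2 units.  ``effect_table`` maps a
    contrast id to (number of planted genes, effect size); planted genes
    are shifted by the effect on every array whose tissue lies in the
    contrast's group.
    """

    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (3, 35)
    tissue_set: tuple[str, ...] = WHORL_ORDER
    n_populations: int = 3
    grid_shape: tuple[int, int] | None = None
    effect_table: dict[int, tuple[int, float]] = field(default_factory=dict)
    baseline_mean: float = 8.0
    gene_sd: float = 1.0
    probe_affinity_sd: float = 0.5
    population_sd: float = 0.25
    noise_sd: float = 0.25
    spatial_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gene_sd", "probe_affinity_sd", "population_sd", "noise_sd",
            "spatial_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must satisfy 1 <= min <= max")
        n_planted = sum(n for n, _ in self.effect_table.values())
        if n_planted > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.n_populations < 2:
            raise ValueError("need >=2 population blocks")


@dataclass
class SimulationTruth:
    """Planted ground truth: which genes carry which contrast effect."""

    genes: pd.DataFrame  # gene_id, contrast_id (-1 = none), direction, effect
    enriched_categories: pd.DataFrame | None = None  # go_id, contrast_id, direction

    def planted_genes(self, contrast_id: int | None = None) -> list[str]:
        g = self.genes[self.genes["contrast_id"] >= 0]
        if contrast_id is not None:
            g = g[g["contrast_id"] == contrast_id]
        return g["gene_id"].tolist()


def generate_study(
    params: SimulationParams,
) -> tuple[list[ProbeIntensityTable], StudyDesign, SimulationTruth]:
    """Generate one probe-level study: one array per (tissue, block)."""
    rng = np.random.default_rng(params.seed)
    contrasts = {c.id: c for c in make_contrasts(params.tissue_set)}
    for cid in params.effect_table:
        if cid not in contrasts:
            raise ValueError(
                f"planted contrast {cid} is not defined for tissue set "
                f"{list(params.tissue_set)}"
            )

    n_genes = params.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    lo, hi = params.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n_genes)
    gene_of_probe = np.repeat(np.arange(n_genes), n_probes_per_gene)
    n_probes = int(n_probes_per_gene.sum())
    probe_ids = np.array(
        [
            f"{gene_ids[g]}_P{j:02d}"
            for g, k in zip(range(n_genes), n_probes_per_gene)
            for j in range(k)
        ]
    )

    # grid layout: random distinct cells, 1-based coordinates
    if params.grid_shape is None:
        side = int(np.ceil(np.sqrt(n_probes)))
        grid_shape = (side, side)
    else:
        grid_shape = tuple(params.grid_shape)
    n_cells = grid_shape[0] * grid_shape[1]
    if n_cells < n_probes:
        raise ValueError(f"grid {grid_shape} too small for {n_probes} probes")
    cells = rng.choice(n_cells, size=n_probes, replace=False)
    xs = (cells % grid_shape[0]) + 1
    ys = (cells // grid_shape[0]) + 1

    baseline = params.baseline_mean + rng.normal(0, params.gene_sd, n_genes)
    affinity = rng.normal(0, params.probe_affinity_sd, n_probes)

    # planted effects: disjoint genes drawn in a fixed shuffled order
    planted_contrast = np.full(n_genes, -1)
    planted_effect = np.zeros(n_genes)
    order = rng.permutation(n_genes)
    cursor = 0
    for cid in sorted(params.effect_table):
        n_pl, eff = params.effect_table[cid]
        chosen = order[cursor : cursor + n_pl]
        cursor += n_pl
        planted_contrast[chosen] = cid
        planted_effect[chosen] = eff

    pops = [f"pop{p + 1}" for p in range(params.n_populations)]
    block_effect = rng.normal(
        0, params.population_sd, (n_genes, params.n_populations)
    )

    entries = []
    tables = []
    xnorm = xs / grid_shape[0]
    ynorm = ys / grid_shape[1]
    for tissue in params.tissue_set:
        for p_idx, pop in enumerate(pops):
            array_id = f"{tissue}_{pop}"
            entries.append((array_id, tissue, pop))
            log2 = baseline[gene_of_probe] + affinity.copy()
            for cid, c in contrasts.items():
                if tissue in c.group:
                    mask = planted_contrast[gene_of_probe] == cid
                    log2[mask] += planted_effect[gene_of_probe][mask]
            log2 += block_effect[gene_of_probe, p_idx]
            if params.spatial_amplitude > 0:
                fx = rng.integers(1, 3, size=2)
                fy = rng.integers(1, 3, size=2)
                phase = rng.uniform(0, 2 * np.pi, size=2)
                surface = 0.5 * params.spatial_amplitude * (
                    np.cos(2 * np.pi * (fx[0] * xnorm + fy[0] * ynorm) + phase[0])
                    + np.cos(2 * np.pi * (fx[1] * xnorm + fy[1] * ynorm) + phase[1])
                )
                log2 += surface
            if params.noise_sd > 0:
                log2 += rng.normal(0, params.noise_sd, n_probes)
            records = pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "gene_id": gene_ids[gene_of_probe],
                    "x": xs,
                    "y": ys,
                    "intensity": np.exp2(log2),
                }
            )
            tables.append(
                ProbeIntensityTable(
                    array_id=array_id, records=records, grid_shape=grid_shape
                )
            )

    design = StudyDesign(
        entries=pd.DataFrame(
            entries, columns=["array_id", "tissue", "population"]
        ),
        species_tag="synthetic",
        tissue_set=tuple(params.tissue_set),
    )
    direction = np.sign(planted_effect).astype(int)
    truth = SimulationTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "contrast_id": planted_contrast,
                "direction": direction,
                "effect": planted_effect,
            }
        )
    )
    return tables, design, truth


def generate_go_annotations(
    gene_ids,
    n_categories: int,
    size_range: tuple[int, int] = (10, 30),
    planted=(),
    seed: int = 0,
    truth: SimulationTruth | None = None,
) -> tuple[GOAnnotationTable, pd.DataFrame]:
    """Random GO membership with optionally planted enriched categories.

    ``planted`` is a sequence of (go_id, contrast_id, n_members); members
    of a planted category are drawn preferentially from genes planted on
    that contrast (per ``truth``), so the category's mean D shifts in the
    planted direction.  Returns the annotation table and a truth frame
    (go_id, contrast_id, direction) for the planted categories.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(list(gene_ids))
    lo, hi = size_range
    if lo < 1:
        raise ValueError("size_range min must be >= 1")
    rows = []
    truth_rows = []
    for go_id, contrast_id, n_members in planted:
        if n_members > len(gene_ids):
            raise ValueError(
                f"category {go_id}: requested {n_members} members but only "
                f"{len(gene_ids)} genes are eligible"
            )
        pool = np.array([], dtype=gene_ids.dtype)
        if truth is not None:
            tg = truth.genes
            pl = tg.loc[tg["contrast_id"] == contrast_id, "gene_id"].to_numpy()
            pool = pl[np.isin(pl, gene_ids)]
        take = min(n_members, len(pool))
        members = list(rng.choice(pool, size=take, replace=False)) if take else []
        if take < n_members:
            rest = gene_ids[~np.isin(gene_ids, members)]
            members += list(
                rng.choice(rest, size=n_members - take, replace=False)
            )
        for g in members:
            rows.append((g, go_id, f"planted category for contrast {contrast_id}"))
        direction = 1
        if truth is not None and take:
            d = truth.genes.set_index("gene_id").loc[members[0], "direction"]
            direction = int(d) if int(d) != 0 else 1
        truth_rows.append((go_id, contrast_id, direction))
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        if size > len(gene_ids):
            raise ValueError(
                f"random category size {size} exceeds {len(gene_ids)} genes"
            )
        go_id = f"GO:{1000000 + i:07d}"
        members = rng.choice(gene_ids, size=size, replace=False)
        for g in members:
            rows.append((g, go_id, f"simulated process {i}"))
    records = pd.DataFrame(rows, columns=["gene_id", "go_id", "go_description"])
    records = records.drop_duplicates(subset=["gene_id", "go_id"])
    table = GOAnnotationTable(records=records.reset_index(drop=True))
    truth_frame = pd.DataFrame(
        truth_rows, columns=["go_id", "contrast_id", "direction"]
    )
    return table, truth_frame


def generate_homolog_hits(
    genes_a,
    genes_b,
    n_true_pairs: int,
    decoy_rate: float = 0.2,
    seed: int = 0,
    e_threshold_ab: float = 5e-6,
    e_threshold_ba: float = 7e-6,
) -> tuple[AlignmentHits, AlignmentHits, pd.DataFrame]:
    """Two directional hit tables whose reciprocal best hits are known.

    True pairs receive mutually best E-values (<= 1e-8) in both
    directions.  Decoys -- weaker secondary hits and one-directional hits,
    some beyond the threshold -- are constructed so that no spurious
    reciprocal best pair can arise.  Returns (hits_ab, hits_ba,
    truth pairs).
    """
    rng = np.random.default_rng(seed)
    genes_a = np.asarray(list(genes_a))
    genes_b = np.asarray(list(genes_b))
    if n_true_pairs > min(len(genes_a), len(genes_b)):
        raise ValueError("n_true_pairs exceeds the smaller gene set")
    pa = rng.permutation(genes_a)[:n_true_pairs]
    pb = rng.permutation(genes_b)[:n_true_pairs]

    ab_rows, ba_rows = [], []
    for a, b in zip(pa, pb):
        e_ab = 10.0 ** (-rng.uniform(8, 30))
        e_ba = 10.0 ** (-rng.uniform(8, 30))
        bit = rng.uniform(100, 500)
        ab_rows.append((a, b, e_ab, bit))
        ba_rows.append((b, a, e_ba, bit))

    # decoys in a->b: any query, E-value in (1e-7.5, 1e-5]; strictly worse
    # than every true pair's E-value, so best hits are never displaced
    n_decoy_ab = int(decoy_rate * len(genes_a))
    for _ in range(n_decoy_ab):
        a = rng.choice(genes_a)
        b = rng.choice(genes_b)
        e = 10.0 ** (-rng.uniform(5.0, 7.5))
        ab_rows.append((a, b, e, rng.uniform(30, 90)))
    # decoys in b->a: only queries that already have a true partner, so an
    # unpaired b never acquires a best hit
    n_decoy_ba = int(decoy_rate * n_true_pairs)
    if n_true_pairs:
        for _ in range(n_decoy_ba):
            b = rng.choice(pb)
            a = rng.choice(genes_a)
            e = 10.0 ** (-rng.uniform(5.0, 7.5))
            ba_rows.append((b, a, e, rng.uniform(30, 90)))

    def frame(rows):
        return pd.DataFrame(
            rows, columns=["query_id", "subject_id", "e_value", "bit_score"]
        )

    hits_ab = AlignmentHits(
        direction_tag="a_vs_b", records=frame(ab_rows), e_threshold=e_threshold_ab
    )
    hits_ba = AlignmentHits(
        direction_tag="b_vs_a", records=frame(ba_rows), e_threshold=e_threshold_ba
    )
    truth = pd.DataFrame({"gene_a": pa, "gene_b": pb}).sort_values(
        "gene_a"
    ).reset_index(drop=True)
    return hits_ab, hits_ba, truth
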