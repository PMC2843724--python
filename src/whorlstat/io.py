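"""Readers and writers for the tabular formats the pipeline touches.

All formats are plain TSV.  Probe-level intensities use a NimbleGen-style
``.pair`` dialect: tab-separated, ``#``-prefixed comment lines, a header
row, required columns PROBE_ID, SEQ_ID, X, Y, PM (extra columns are
ignored).  Alignment hits use BLAST tabular output (``-outfmt 6``,
12 columns).  Parsers never reorder records and validate strictly,
reporting the offending column or line.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical whorl order, outermost to innermost.  STD (staminodia) is the
#: fifth whorl present in Aquilegia but absent from the four-whorl
#: Arabidopsis design.
WHORL_ORDER = ("SEP", "PET", "STA", "STD", "CAR")

_GO_ID_RE = re.compile(r"^GO[:.]\d{7}$")

PAIR_COLUMNS = ("PROBE_ID", "SEQ_ID", "X", "Y", "PM")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class DesignError(ValueError):
    """A study-design table violates its invariants."""


@dataclass
class ProbeIntensityTable:
    """Probe-level intensities for one array.

    ``records`` has columns ``probe_id, gene_id, x, y, intensity`` in file
    order; ``grid_shape`` is the (max_x, max_y) bound of the 1-based probe
    grid.
    """

    array_id: str
    records: pd.DataFrame
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        req = ["probe_id", "gene_id", "x", "y", "intensity"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise FormatError(f"probe table missing columns: {missing}")
        if self.records["probe_id"].duplicated().any():
            dups = self.records.loc[
                self.records["probe_id"].duplicated(), "probe_id"
            ].tolist()
            raise FormatError(
                f"duplicate probe ids on array {self.array_id!r}: {dups[:5]}"
            )
        if (self.records["intensity"] < 0).any():
            raise FormatError(f"negative intensity on array {self.array_id!r}")
        if len(self.records):
            mx, my = self.grid_shape
            if (self.records["x"] > mx).any() or (self.records["y"] > my).any():
                raise FormatError(
                    f"probe coordinates exceed grid bounds {self.grid_shape}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StudyDesign:
    """Array-to-sample assignment: which whorl and population block each
    array measures."""

    entries: pd.DataFrame  # columns array_id, tissue, population
    species_tag: str = ""
    tissue_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        req = ["array_id", "tissue", "population"]
        missing = [c for c in req if c not in self.entries.columns]
        if missing:
            raise DesignError(f"design missing columns: {missing}")
        dup = self.entries.duplicated(subset=["tissue", "population"])
        if dup.any():
            pairs = self.entries.loc[dup, ["tissue", "population"]].values.tolist()
            raise DesignError(f"duplicate (tissue, population) pairs: {pairs}")
        if self.entries["array_id"].duplicated().any():
            raise DesignError("duplicate array_id in design")
        if not self.tissue_set:
            self.tissue_set = canonical_tissue_set(self.entries["tissue"])
        unknown = set(self.entries["tissue"]) - set(self.tissue_set)
        if unknown:
            raise DesignError(
                f"unknown tissue labels {sorted(unknown)}; allowed: "
                f"{list(self.tissue_set)}"
            )
        if len(self.tissue_set) not in (4, 5):
            raise DesignError(
                f"tissue_set must have 4 or 5 whorls, got {list(self.tissue_set)}"
            )

    @property
    def array_ids(self) -> list[str]:
        return self.entries["array_id"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.entries["population"].unique())

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.entries["array_id"], self.entries["tissue"]))

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.entries["array_id"], self.entries["population"]))


def canonical_tissue_set(tissues) -> tuple[str, ...]:
    """Order the observed whorl labels canonically (SEP, PET, STA, STD, CAR)."""
    seen = set(tissues)
    unknown = seen - set(WHORL_ORDER)
    if unknown:
        raise DesignError(
            f"unknown tissue labels {sorted(unknown)}; allowed: {list(WHORL_ORDER)}"
        )
    return tuple(t for t in WHORL_ORDER if t in seen)


@dataclass
class GOAnnotationTable:
    """Gene -> GO biological-process assignments, de-duplicated."""

    records: pd.DataFrame  # columns gene_id, go_id, go_description

    @property
    def n_genes(self) -> int:
        return self.records["gene_id"].nunique()

    @property
    def n_categories(self) -> int:
        return self.records["go_id"].nunique()


@dataclass
class AlignmentHits:
    """One direction of a BLAST-tabular search with its E-value threshold.

    All parsed rows are retained; the inclusive threshold is applied only
    when reciprocal pairs are derived, so out-of-threshold hits can be
    inspected rather than silently dropped.
    """

    direction_tag: str
    records: pd.DataFrame  # columns query_id, subject_id, e_value, bit_score
    e_threshold: float

    def __post_init__(self) -> None:
        if self.e_threshold < 0:
            raise ValueError("e_threshold must be nonnegative")
        if len(self.records) and (self.records["e_value"] < 0).any():
            raise FormatError("negative E-value in hit table")

    def within_threshold(self) -> pd.DataFrame:
        return self.records[self.records["e_value"] <= self.e_threshold]


def normalize_go_id(go_id: str) -> str:
    """Canonicalize a GO identifier: ``GO.0006118`` and ``GO:0006118`` are
    the same term, stored with ``:``.  Malformed ids produce a warning and
    are kept as-is."""
    go_id = go_id.strip()
    if _GO_ID_RE.match(go_id):
        return "GO:" + go_id[3:]
    warnings.warn(f"malformed GO id kept verbatim: {go_id!r}", stacklevel=2)
    return go_id


# ---------------------------------------------------------------------------
# readers


def _read_tsv_lines(path) -> list[tuple[int, list[str]]]:
    """Non-comment, non-blank lines of a TSV file as (1-based line number,
    fields)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((i, line.split("\t")))
    return out


def read_pair_file(path, array_id: str | None = None) -> ProbeIntensityTable:
    """Read a ``.pair``-style probe intensity file.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header naming at least PROBE_ID, SEQ_ID,
        X, Y, PM; ``#`` lines are comments.
    array_id : str, optional
        Label for the array; defaults to the file stem.
    """
    import os

    if array_id is None:
        array_id = os.path.splitext(os.path.basename(str(path)))[0]
    lines = _read_tsv_lines(path)
    if not lines:
        raise FormatError(f"{path}: no header row")
    _, header = lines[0]
    missing = [c for c in PAIR_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in PAIR_COLUMNS}
    probes, genes, xs, ys, pms = [], [], [], [], []
    for lineno, fields in lines[1:]:
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
        try:
            x = int(fields[idx["X"]])
            y = int(fields[idx["Y"]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer grid coordinate") from exc
        try:
            pm = float(fields[idx["PM"]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric intensity") from exc
        probes.append(fields[idx["PROBE_ID"]])
        genes.append(fields[idx["SEQ_ID"]])
        xs.append(x)
        ys.append(y)
        pms.append(pm)
    records = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_id": genes,
            "x": np.asarray(xs, dtype=int),
            "y": np.asarray(ys, dtype=int),
            "intensity": np.asarray(pms, dtype=float),
        }
    )
    if len(records):
        grid = (int(records["x"].max()), int(records["y"].max()))
    else:
        grid = (0, 0)
    return ProbeIntensityTable(array_id=array_id, records=records, grid_shape=grid)


def write_pair_file(table: ProbeIntensityTable, path, comment: str = "") -> None:
    """Write a probe table back in the ``.pair`` dialect (round-trips with
    :func:`read_pair_file`)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for rec in table.records.itertuples(index=False):
            fh.write(
                f"{rec.probe_id}\t{rec.gene_id}\t{rec.x}\t{rec.y}\t"
                f"{rec.intensity:.10g}\n"
            )


def read_design(path, species_tag: str = "") -> StudyDesign:
    """Read a study-design TSV with columns array_id, tissue, population."""
    lines = _read_tsv_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty design file")
    _, header = lines[0]
    for col in ("array_id", "tissue", "population"):
        if col not in header:
            raise FormatError(f"{path}: missing required column(s) ['{col}']")
    idx = {c: header.index(c) for c in ("array_id", "tissue", "population")}
    rows = [
        (f[idx["array_id"]], f[idx["tissue"]], f[idx["population"]])
        for _, f in lines[1:]
    ]
    entries = pd.DataFrame(rows, columns=["array_id", "tissue", "population"])
    return StudyDesign(entries=entries, species_tag=species_tag)


def write_design(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("array_id\ttissue\tpopulation\n")
        for rec in design.entries.itertuples(index=False):
            fh.write(f"{rec.array_id}\t{rec.tissue}\t{rec.population}\n")


def read_go_annotations(path) -> GOAnnotationTable:
    """Read a gene -> GO TSV (gene_id, go_id, optional description);
    duplicate (gene, term) pairs are dropped, GO ids canonicalized."""
    lines = _read_tsv_lines(path)
    if not lines:
        return GOAnnotationTable(
            records=pd.DataFrame(columns=["gene_id", "go_id", "go_description"])
        )
    _, header = lines[0]
    for col in ("gene_id", "go_id"):
        if col not in header:
            raise FormatError(f"{path}: missing required column(s) ['{col}']")
    gi, ti = header.index("gene_id"), header.index("go_id")
    di = header.index("go_description") if "go_description" in header else None
    rows = []
    for _, f in lines[1:]:
        desc = f[di] if di is not None and di < len(f) else ""
        rows.append((f[gi], normalize_go_id(f[ti]), desc))
    records = pd.DataFrame(rows, columns=["gene_id", "go_id", "go_description"])
    records = records.drop_duplicates(subset=["gene_id", "go_id"], keep="first")
    return GOAnnotationTable(records=records.reset_index(drop=True))


def write_go_annotations(table: GOAnnotationTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_hit_table(path, e_threshold: float, direction_tag: str = "") -> AlignmentHits:
    """Read BLAST tabular output (``-outfmt 6``: qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    queries, subjects, evalues, bits = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                ev = float(fields[10])
                bs = float(fields[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable evalue/bitscore"
                ) from exc
            queries.append(fields[0])
            subjects.append(fields[1])
            evalues.append(ev)
            bits.append(bs)
    records = pd.DataFrame(
        {
            "query_id": queries,
            "subject_id": subjects,
            "e_value": np.asarray(evalues, dtype=float),
            "bit_score": np.asarray(bits, dtype=float),
        }
    )
    return AlignmentHits(
        direction_tag=direction_tag or str(path),
        records=records,
        e_threshold=float(e_threshold),
    )


def write_hit_table(hits: AlignmentHits, path) -> None:
    """Write hits in 12-column BLAST tabular form (unused columns zeroed)."""
    with open(path, "w") as fh:
        for rec in hits.records.itertuples(index=False):
            fh.write(
                f"{rec.query_id}\t{rec.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{rec.e_value:.3g}\t{rec.bit_score:.1f}\n"
            )


def write_tsv(frame: pd.DataFrame, path, provenance: str = "") -> None:
    """Write a result table with a one-line ``#`` provenance header."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t", index=False)
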