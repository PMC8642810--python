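"""Readers, writers and validated in-memory containers.

All tabular formats are tab-delimited UTF-8 text with a header row.  Gene
and sample identifiers are opaque strings; no symbol mapping is attempted.
Parsers validate eagerly and raise :class:`FormatError` (malformed file,
with coordinates where possible) or :class:`ValidationError` (well-formed
file violating an invariant) rather than coercing silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """A parsed object violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Raw gene x sample integer read counts with gene lengths.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``counts``.
    gene_lengths_bp : ndarray of int
        Transcript length in base pairs per gene, all >= 1.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_genes, n_samples)
        Non-negative read counts.
    sample_groups : dict
        sample_id -> group label (cancer type or normal tissue name).
    """

    gene_ids: list
    gene_lengths_bp: np.ndarray
    sample_ids: list
    counts: np.ndarray
    sample_groups: dict

    def __post_init__(self):
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.gene_lengths_bp = np.asarray(self.gene_lengths_bp, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.floor(self.counts)
            ):
                raise ValidationError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be >= 0")
        if np.any(self.gene_lengths_bp < 1):
            bad = self.gene_ids[int(np.argmax(self.gene_lengths_bp < 1))]
            raise ValidationError(f"gene length < 1 bp for gene {bad!r}")
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets; each set an ordered, deduplicated list of gene ids."""

    sets: dict

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} contains duplicates")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class SurvivalTable:
    """Right-censored survival records keyed by sample id."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    metastatic: np.ndarray | None = None

    def __post_init__(self):
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (np.all(np.isfinite(self.time)) and np.all(self.time >= 0)):
            raise ValidationError("survival times must be finite and >= 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValidationError("event must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(np.int64)
        if self.metastatic is not None:
            self.metastatic = np.asarray(self.metastatic)
            if not np.all(np.isin(self.metastatic, [0, 1])):
                raise ValidationError("metastatic flag must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "event": self.event}
        if self.metastatic is not None:
            d["metastatic"] = self.metastatic
        return pd.DataFrame(d, index=self.sample_ids)


@dataclass
class CloneTable:
    """TCR-beta clonotypes of one sample, keyed by CDR3 amino-acid sequence.

    Clones with identical CDR3 amino-acid sequence are merged by summing
    read counts (nucleotide-level convergence is collapsed upstream).
    """

    sample_id: str
    clones: dict  # cdr3_aa -> count
    total_sample_reads: int | None = None
    n_discarded: int = 0

    def __post_init__(self):
        if len(self.clones) == 0:
            raise ValidationError(f"sample {self.sample_id!r} has no valid clones")
        for cdr3, count in self.clones.items():
            if not cdr3 or not set(cdr3) <= AMINO_ACIDS:
                raise ValidationError(f"invalid CDR3 sequence {cdr3!r}")
            if count < 1:
                raise ValidationError(f"clone {cdr3!r} has count {count} < 1")
        if self.total_sample_reads is not None and self.total_sample_reads < 1:
            raise ValidationError("total_sample_reads must be positive")

    @property
    def total_tcr_reads(self) -> int:
        return sum(self.clones.values())


@dataclass
class ReferenceCdr3Set:
    """A named reference collection of CDR3 amino-acid sequences."""

    name: str
    sequences: set

    def __post_init__(self):
        self.sequences = set(self.sequences)
        for s in self.sequences:
            if not s or not set(s) <= AMINO_ACIDS:
                raise ValidationError(f"invalid CDR3 sequence {s!r} in {self.name!r}")


# ---------------------------------------------------------------------------
# Count matrix TSV: gene_id <TAB> length <TAB> sample1 <TAB> sample2 ...
# ---------------------------------------------------------------------------

def read_count_matrix(path, annotation_path) -> CountMatrix:
    """Read a genes-in-rows count matrix plus a sample annotation table.

    The matrix file has a header ``gene_id, length, <sample ids...>``; the
    annotation file has columns ``sample_id, group``.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise FormatError(
                "count matrix header needs gene id, length and >= 1 sample column"
            )
        sample_ids = header[2:]
        _check_unique(sample_ids, "sample")
        gene_ids, lengths, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                lengths.append(int(fields[1]))
            except ValueError:
                raise FormatError(
                    f"line {lineno}, column 2: non-integer gene length {fields[1]!r}"
                ) from None
            row = []
            for col, cell in enumerate(fields[2:], start=3):
                try:
                    value = int(cell)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}, column {col}: non-integer count {cell!r}"
                    ) from None
                if value < 0:
                    raise FormatError(
                        f"line {lineno}, column {col}: negative count {cell!r}"
                    )
                row.append(value)
            rows.append(row)
    _check_unique(gene_ids, "gene")
    groups = read_sample_annotation(annotation_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"samples missing from annotation: {missing}")
    return CountMatrix(
        gene_ids=gene_ids,
        gene_lengths_bp=np.array(lengths, dtype=np.int64),
        sample_ids=sample_ids,
        counts=np.array(rows, dtype=np.int64).reshape(len(gene_ids), len(sample_ids)),
        sample_groups={s: groups[s] for s in sample_ids},
    )


def write_count_matrix(cm: CountMatrix, path, annotation_path=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlength\t" + "\t".join(cm.sample_ids) + "\n")
        for g, L, row in zip(cm.gene_ids, cm.gene_lengths_bp, cm.counts):
            fh.write(f"{g}\t{L}\t" + "\t".join(str(int(x)) for x in row) + "\n")
    if annotation_path is not None:
        write_sample_annotation(cm.sample_groups, annotation_path)


def read_sample_annotation(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    _check_unique(df["sample_id"], "sample")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_annotation(groups: dict, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, then gene ids)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT line needs name, description and >= 1 gene"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValidationError(f"line {lineno}: set {name!r} empty after dedup")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# Survival TSV: sample_id, time, event[, metastatic]
# ---------------------------------------------------------------------------

def read_survival_table(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival file missing column {col!r}")
    met = df["metastatic"].to_numpy() if "metastatic" in df.columns else None
    return SurvivalTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
        metastatic=met,
    )


def write_survival_table(surv: SurvivalTable, path) -> None:
    surv.to_frame().rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Clone table TSV (VDJtools-style): count, cdr3aa columns (configurable)
# ---------------------------------------------------------------------------

def read_clone_table(
    path,
    sample_id: str | None = None,
    count_col: str = "count",
    cdr3_col: str = "cdr3aa",
    total_sample_reads: int | None = None,
) -> CloneTable:
    """Read a per-sample clonotype table.

    Rows with the same CDR3 amino-acid sequence are merged by summing
    counts.  Rows whose CDR3 contains a character outside the 20-letter
    amino-acid alphabet (stop codons ``*``, frameshift markers ``_``, ...)
    are dropped; the number dropped is recorded in ``n_discarded``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"clone table {path} is empty") from None
    for col in (count_col, cdr3_col):
        if col not in df.columns:
            raise FormatError(f"clone table missing required column {col!r}")
    clones: dict = {}
    n_discarded = 0
    for lineno, (cdr3, count) in enumerate(
        zip(df[cdr3_col].astype(str), df[count_col]), start=2
    ):
        if not cdr3 or not set(cdr3) <= AMINO_ACIDS:
            n_discarded += 1
            continue
        try:
            count = int(count)
        except (TypeError, ValueError):
            raise FormatError(f"line {lineno}: non-integer count {count!r}") from None
        if count < 1:
            raise FormatError(f"line {lineno}: count {count} < 1")
        clones[cdr3] = clones.get(cdr3, 0) + count
    if not clones:
        raise ValidationError(f"clone table {path} has no valid clones")
    if sample_id is None:
        sample_id = str(path)
    return CloneTable(
        sample_id=sample_id,
        clones=clones,
        total_sample_reads=total_sample_reads,
        n_discarded=n_discarded,
    )


def write_clone_table(table: CloneTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("count\tcdr3aa\n")
        for cdr3, count in table.clones.items():
            fh.write(f"{count}\t{cdr3}\n")


# ---------------------------------------------------------------------------
# Reference CDR3 set: one sequence per line
# ---------------------------------------------------------------------------

def read_reference_cdr3_set(path, name: str | None = None) -> ReferenceCdr3Set:
    with open(path, encoding="utf-8") as fh:
        seqs = {line.strip() for line in fh if line.strip()}
    return ReferenceCdr3Set(name=name or str(path), sequences=seqs)


def write_reference_cdr3_set(ref: ReferenceCdr3Set, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(ref.sequences):
            fh.write(s + "\n")
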