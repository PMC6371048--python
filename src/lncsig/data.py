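"""Core containers and text-format I/O.

Conventions used throughout the package:

* counts are gene × sample integer matrices held as :class:`pandas.DataFrame`
  (rows = gene ids, columns = sample ids);
* gene annotation is a DataFrame indexed by gene id with columns
  ``chrom, start, end, strand, biotype, transcript_length``; coordinates are
  1-based and inclusive at both ends, as in a GFF file;
* expression matrices (vst / FPKM / normalized counts) are float DataFrames
  with the transform recorded in ``df.attrs["kind"]``;
* gene-set collections are ``{term_id: (term_name, set_of_gene_ids)}`` read
  from and written to GMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene_id", "biotype", "strand", "transcript_length"]


@dataclass
class CountMatrix:
    """Integer gene × sample count matrix plus per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by gene id, columns by
        sample id.
    sample_meta
        DataFrame indexed by sample id.  Recognised columns are
        ``condition`` (e.g. LPS / untreated), ``timepoint`` (e.g. t0, t1.5,
        t4) and ``group`` (cohort group label such as HC or dcSSc); any
        subset may be present depending on the design.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts contain negative entries")
        if c.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in counts")
        self.counts = c.rename_axis(index="gene_id")
        if len(self.sample_meta):
            missing = c.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[c.columns].rename_axis(index="sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        meta = self.sample_meta.loc[samples] if len(self.sample_meta) else self.sample_meta
        return CountMatrix(self.counts[samples], meta)

    def write(self, counts_path, meta_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            meta = self.sample_meta.copy()
            meta.index.name = "sample"
            meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path, meta_path=None) -> CountMatrix:
    """Read a counts TSV (gene_id + one column per sample) and optional metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts.astype(int), meta)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation contract: required columns, start ≤ end, positive lengths."""
    required = {"chrom", "start", "end", "strand", "biotype", "transcript_length"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("annotation has start > end")
    if (annotation["transcript_length"] <= 0).any():
        raise ValueError("annotation has non-positive transcript_length")
    return annotation


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like annotation TSV (1-based inclusive coordinates).

    Columns: chrom, start, end, gene_id, biotype, strand, transcript_length.
    """
    ann = pd.read_csv(path, sep="\t")
    ann = ann.set_index("gene_id")
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index().rename(columns={"index": "gene_id"})
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into {term_id: (description, gene set)}."""
    terms: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, desc, genes = fields[0], fields[1], fields[2:]
        if term_id in terms:
            raise ValueError(f"duplicate term id {term_id!r}")
        genes = {g for g in genes if g}
        if not genes:
            raise ValueError(f"empty gene set for term {term_id!r}")
        terms[term_id] = (desc, genes)
    return terms


def write_gmt(terms: Mapping[str, tuple[str, set[str]]], path) -> None:
    lines = []
    for term_id, (desc, genes) in terms.items():
        lines.append("\t".join([term_id, desc] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")
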