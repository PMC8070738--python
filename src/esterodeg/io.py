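"""Readers and writers for every table the pipeline consumes or emits.

All tabular formats are tab-separated with a header row, UTF-8, '.' decimal
and no quoting of numeric fields; every writer round-trips bit-exactly with
its reader.  GFF3 gene models are read 1-based inclusive (gene length =
end - start + 1) and overlapping same-strand gene pairs are detected with
the shared span in bp.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import CountMatrix

_TSV = dict(sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# counts / annotation / design
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path, annot_path, design_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, **_TSV)
    annot = pd.DataFrame(
        {"gene_id": cm.counts.index,
         "length_bp": cm.gene_lengths.loc[cm.counts.index].to_numpy()}
    )
    annot.to_csv(annot_path, index=False, **_TSV)
    design = pd.DataFrame(
        {"sample_id": list(cm.counts.columns),
         "strain": [cm.design[s] for s in cm.counts.columns]}
    )
    design.to_csv(design_path, index=False, **_TSV)


def read_counts(counts_path, annot_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, index_col="gene_id", **_TSV)
    annot = pd.read_csv(annot_path, **_TSV).set_index("gene_id")
    design_df = pd.read_csv(design_path, **_TSV)
    design = dict(zip(design_df["sample_id"], design_df["strain"]))
    return CountMatrix(
        counts=counts, gene_lengths=annot["length_bp"], design=design
    )


def write_region_counts(region_counts: pd.DataFrame, path) -> None:
    region_counts.to_csv(path, index=False, **_TSV)


def read_region_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, **_TSV)


# ---------------------------------------------------------------------------
# GO / PPI / histone / gene classes
# ---------------------------------------------------------------------------

def write_go_annotation(annot: pd.DataFrame, path) -> None:
    annot[["gene_id", "term_id"]].to_csv(path, index=False, **_TSV)


def read_go_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, **_TSV)


def write_ppi_edges(matrix: pd.DataFrame, path) -> None:
    """Write the upper triangle of a symmetric score matrix as an edge list."""
    ids = list(matrix.index)
    rows = [
        (ids[i], ids[j], matrix.iat[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).to_csv(
        path, index=False, **_TSV
    )


def read_ppi_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, **_TSV)


def write_histone_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("gene_id").to_csv(path, **_TSV)


def read_histone_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="gene_id", **_TSV)


def write_gene_classes(classes: pd.Series, path) -> None:
    classes.rename("gene_class").rename_axis("gene_id").to_csv(path, **_TSV)


def read_gene_classes(path) -> pd.Series:
    return pd.read_csv(path, index_col="gene_id", **_TSV)["gene_class"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotype(loci: dict[str, str], path) -> None:
    pd.DataFrame({"locus": list(loci), "state": list(loci.values())}).to_csv(
        path, index=False, **_TSV
    )


def read_genotype(path) -> dict[str, str]:
    df = pd.read_csv(path, **_TSV)
    return dict(zip(df["locus"], df["state"]))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

class GFF3Error(ValueError):
    """Malformed GFF3 input, carrying the offending line number."""


def read_gff3(path, feature_type: str = "gene"):
    """Gene spans and overlapping same-strand pairs from a GFF3 file.

    Returns (annotation, overlaps): ``annotation`` has one row per gene
    (gene_id, chrom, start, end, strand, length_bp with length
    = end - start + 1, 1-based inclusive); ``overlaps`` lists same-strand
    overlapping gene pairs with the shared span in bp.
    """
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3Error(f"line {lineno}: expected 9 tab-separated fields, "
                                f"got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GFF3Error(f"line {lineno}: non-integer coordinates") from exc
            if start_i > end_i or start_i < 1:
                raise GFF3Error(f"line {lineno}: invalid interval {start}-{end}")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if not gene_id:
                raise GFF3Error(f"line {lineno}: feature without ID attribute")
            genes.append((gene_id, chrom, start_i, end_i, strand,
                          end_i - start_i + 1))
    annotation = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "length_bp"]
    )
    overlaps = []
    by_key = annotation.groupby(["chrom", "strand"], sort=False)
    for _, grp in by_key:
        g = grp.sort_values("start").reset_index(drop=True)
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                if g.loc[j, "start"] > g.loc[i, "end"]:
                    break
                shared = min(g.loc[i, "end"], g.loc[j, "end"]) - g.loc[j, "start"] + 1
                if shared > 0:
                    overlaps.append((g.loc[i, "gene_id"], g.loc[j, "gene_id"],
                                     int(shared)))
    overlap_df = pd.DataFrame(overlaps, columns=["gene_a", "gene_b", "shared_bp"])
    return annotation, overlap_df


def write_gff3(annotation: pd.DataFrame, path, feature_type: str = "gene",
               source: str = "esterodeg") -> None:
    """Write gene spans back out as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\t{feature_type}\t{row.start}\t{row.end}"
                f"\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# JSON summaries
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
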