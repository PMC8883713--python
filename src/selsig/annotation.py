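"""Gene annotation of candidate regions and hypergeometric term enrichment.

Annotation comes from a local BED4 or GFF3 file (gene features); term
membership from a two-column TSV (term_id, gene_id) with an optional
term-name table. Gene coordinates are 1-based inclusive internally; BED
input is converted from 0-based half-open. A gene overlaps a region when
they share at least one bp (book-ended contact does not count, unlike
interval merging).

Enrichment is the plain hypergeometric over-representation test
P(X >= k) for k query hits among a K-gene term drawn n times from an
N-gene background, with Benjamini-Hochberg FDR across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GENE_COLUMNS = ["gene_id", "name", "chrom", "start_bp", "end_bp", "strand"]


def read_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene models from BED4(+) or GFF3 into a sorted DataFrame."""
    path = Path(path)
    if fmt is None:
        fmt = "GFF3" if path.suffix.lower() in (".gff", ".gff3") else "BED"
    fmt = fmt.upper()
    if fmt == "BED":
        genes = _read_bed(path)
    elif fmt == "GFF3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if (genes["start_bp"] > genes["end_bp"]).any():
        bad = genes[genes["start_bp"] > genes["end_bp"]].iloc[0]
        raise ValueError(f"gene {bad.gene_id}: start > end")
    return genes.sort_values(["chrom", "start_bp"],
                             kind="stable").reset_index(drop=True)


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad coordinate") from e
            name = parts[3] if len(parts) > 3 else f"gene{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append({
                "gene_id": name, "name": name, "chrom": parts[0],
                "start_bp": start0 + 1, "end_bp": end0, "strand": strand,
            })
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        name = feat.attributes.get("Name", [feat.id])[0]
        rows.append({
            "gene_id": feat.id, "name": name, "chrom": feat.seqid,
            "start_bp": feat.start, "end_bp": feat.end,
            "strand": feat.strand or ".",
        })
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}"
                f"\t0\t{g.strand}\n"
            )


def genes_in_region(region, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes sharing >= 1 bp with the region, ordered by start position."""
    hit = genes[
        (genes["chrom"].astype(str) == str(region.chrom))
        & (genes["start_bp"] <= region.end_bp)
        & (genes["end_bp"] >= region.start_bp)
    ]
    return hit.drop_duplicates("gene_id").sort_values(
        ["start_bp", "gene_id"], kind="stable"
    ).reset_index(drop=True)


def closest_gene(chrom: str, position: int, genes: pd.DataFrame):
    """Nearest gene on the chromosome: (gene row, distance_bp) or None.

    Distance is 0 inside a gene, else the minimum boundary distance;
    ties break toward the smaller start position.
    """
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return None
    start = sub["start_bp"].to_numpy()
    end = sub["end_bp"].to_numpy()
    dist = np.where(
        (position >= start) & (position <= end), 0,
        np.minimum(np.abs(start - position), np.abs(end - position)),
    )
    order = np.lexsort((start, dist))
    best = order[0]
    return sub.iloc[best], int(dist[best])


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr_bh: float = np.nan


def read_term_map(path: str | Path) -> dict[str, set]:
    """Two-column TSV (term_id, gene_id) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                     dtype=str, comment="#")
    return {t: set(sub["gene_id"]) for t, sub in df.groupby("term_id")}


def hypergeometric_enrichment(
    query_genes,
    term_map: dict[str, set],
    background_genes,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation of each term in the query gene set.

    p = P(X >= k) under Hypergeometric(N, K, n); terms with no query hit
    are skipped; BH-FDR across the tested terms. The query must be a
    subset of the background.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene set")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & background
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term_id,
            "term_name": (term_names or {}).get(term_id, term_id),
            "k": k, "K": K, "n": n, "N": N, "p_value": min(1.0, p),
        })
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["fdr_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr_bh"] = pd.Series(dtype=float)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
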