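"""Genomic interval model, nearest-TSS peak-to-gene assignment, peak-set overlap.

Coordinates are 0-based half-open throughout (BED convention). GTF input is
1-based inclusive and converted on read, with the TSS taken as the start of
a + strand gene and the end of a − strand gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenomeAnnotation:
    """Per-gene TSS records: columns ``gene_id, chrom, strand, tss`` (0-based)."""

    genes: pd.DataFrame
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            dupes = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {list(dupes.unique()[:5])}")
        if self.chrom_sizes:
            for chrom, grp in self.genes.groupby("chrom"):
                size = self.chrom_sizes.get(chrom)
                if size is not None and (grp["tss"] >= size).any():
                    raise ValueError(f"TSS beyond end of {chrom}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PeakSet:
    """Peak intervals: columns ``peak_id, chrom, start, end`` (+ optional ``summit``)."""

    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peak_id", "chrom", "start", "end"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peaks with start >= end")

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted(self) -> pd.DataFrame:
        return self.peaks.sort_values(["chrom", "start"], kind="mergesort")


def peak_reference_points(peaks: PeakSet) -> np.ndarray:
    """Per-peak reference coordinate: the summit when present, else the
    interval midpoint ``floor((start + end) / 2)``."""
    df = peaks.peaks
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    if "summit" in df.columns:
        summit = df["summit"].to_numpy(float)
        mid = np.where(np.isnan(summit), mid, summit).astype(np.int64)
    return mid.astype(np.int64)


def nearest_tss(peaks: PeakSet, genes: GenomeAnnotation) -> pd.DataFrame:
    """Assign every peak to the gene with the nearest TSS on its chromosome.

    The reference point of a peak is its summit when present, else its
    midpoint. Signed distance is ``tss − ref`` for + strand genes and
    ``ref − tss`` for − strand genes. Ties in |distance| are broken by the lexicographically smaller
    gene id. Peaks on chromosomes without genes are retained with a null
    gene (so peak denominators are preserved).

    Returns a DataFrame ``peak_id, gene_id, distance`` (gene_id NA where
    unassignable). Raises if no peak chromosome matches any gene chromosome.
    """
    if len(peaks) == 0 or len(genes) == 0:
        raise ValueError("peaks and genes must both be nonempty")
    pk = peaks.peaks.reset_index(drop=True)
    refs = peak_reference_points(peaks)

    peak_chroms = set(pk["chrom"])
    gene_chroms = set(genes.genes["chrom"])
    if not peak_chroms & gene_chroms:
        raise ValueError(
            "no shared chromosomes between peaks and annotation; "
            f"peaks have {sorted(peak_chroms)[:5]}, genes have {sorted(gene_chroms)[:5]}"
        )

    by_chrom = {}
    for chrom, grp in genes.genes.groupby("chrom"):
        g = grp.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[chrom] = (
            g["tss"].to_numpy(np.int64),
            g["gene_id"].to_numpy(object),
            g["strand"].to_numpy(object),
        )

    gene_out = np.full(len(pk), None, dtype=object)
    dist_out = np.full(len(pk), np.nan)
    for chrom, idx in pk.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        tss, gids, strands = by_chrom[chrom]
        idx = np.asarray(idx)
        pos = refs[idx]
        right = np.searchsorted(tss, pos)
        for k, (i, p) in enumerate(zip(idx, pos)):
            r = right[k]
            candidates = []
            if r < len(tss):
                candidates.append(r)
            if r > 0:
                candidates.append(r - 1)
            best_d = min(abs(int(tss[c]) - int(p)) for c in candidates)
            # gather every gene at the minimal |distance| (equidistant TSSs
            # left and right, plus duplicated TSS coordinates), pick min id
            chosen = None
            for side, step in ((r, 1), (r - 1, -1)):
                c = side
                while 0 <= c < len(tss) and abs(int(tss[c]) - int(p)) == best_d:
                    if chosen is None or gids[c] < gids[chosen]:
                        chosen = c
                    c += step
            signed = int(tss[chosen]) - int(p)
            if strands[chosen] == "-":
                signed = -signed
            gene_out[i] = gids[chosen]
            dist_out[i] = signed

    return pd.DataFrame(
        {"peak_id": pk["peak_id"], "gene_id": gene_out, "distance": dist_out}
    )


def shared_peaks(set_a: PeakSet, set_b: PeakSet, min_overlap: int = 1) -> dict:
    """Count peaks of A overlapping any peak of B by >= ``min_overlap`` bp.

    Returns a report dict with ``n_a, n_b, n_shared_a, n_shared_b,
    percent_of_a, percent_of_b`` (percents both to 0.1 and rounded-integer
    form). Overlap counts are asymmetric and both directions are reported.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    def shared_flags(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(a), dtype=bool)
        for chrom, ai in a.groupby("chrom").groups.items():
            bgrp = b[b["chrom"] == chrom]
            if bgrp.empty:
                continue
            order = np.argsort(bgrp["start"].to_numpy(), kind="mergesort")
            bs = bgrp["start"].to_numpy()[order]
            be = bgrp["end"].to_numpy()[order]
            be_cummax = np.maximum.accumulate(be)
            ai = np.asarray(ai)
            a_start = a.loc[ai, "start"].to_numpy()
            a_end = a.loc[ai, "end"].to_numpy()
            # candidate B peaks start before a_end - min_overlap + 1
            hi = np.searchsorted(bs, a_end - min_overlap, side="right")
            for k, i in enumerate(ai):
                j = hi[k]
                if j == 0:
                    continue
                # scan left while some earlier B interval could still reach
                jj = j - 1
                while jj >= 0 and be_cummax[jj] - a_start[k] >= min_overlap:
                    ov = min(a_end[k], be[jj]) - max(a_start[k], bs[jj])
                    if ov >= min_overlap:
                        flags[i] = True
                        break
                    jj -= 1
        return flags

    a, b = set_a.peaks.reset_index(drop=True), set_b.peaks.reset_index(drop=True)
    if len(a) == 0 or len(b) == 0:
        warnings.warn("empty peak set in overlap computation", stacklevel=2)
        return dict(n_a=len(a), n_b=len(b), n_shared_a=0, n_shared_b=0,
                    percent_of_a=0.0, percent_of_b=0.0,
                    percent_of_a_int=0, percent_of_b_int=0)
    fa = shared_flags(a, b)
    fb = shared_flags(b, a)
    pct_a = 100.0 * fa.sum() / len(a)
    pct_b = 100.0 * fb.sum() / len(b)
    return dict(
        n_a=len(a), n_b=len(b),
        n_shared_a=int(fa.sum()), n_shared_b=int(fb.sum()),
        percent_of_a=round(float(pct_a), 1), percent_of_b=round(float(pct_b), 1),
        percent_of_a_int=int(round(pct_a)), percent_of_b_int=int(round(pct_b)),
    )


# ---------------------------------------------------------------------------
# BED / GTF I/O


def read_bed(path) -> PeakSet:
    """Read BED3/BED6 peak intervals (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            rows.append((name, fields[0], start, end))
    return PeakSet(pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"]))


def write_bed(path, peaks: PeakSet) -> None:
    df = peaks.sorted()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\n")


def read_gtf_tss(path, feature: str = "gene") -> GenomeAnnotation:
    """Extract per-gene TSS records from GTF ``gene`` lines.

    GTF is 1-based inclusive; the stored TSS is 0-based: ``start − 1`` for
    + strand genes, ``end − 1`` for − strand genes.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GTF line has {len(fields)} fields, expected 9")
            if fields[2] != feature:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[6]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            gene_id = None
            for attr in fields[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            tss = start - 1 if strand == "+" else end - 1
            rows.append((gene_id, fields[0], strand, tss))
    return GenomeAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]))


def write_gtf_tss(path, genes: GenomeAnnotation, gene_length: int = 1000) -> None:
    """Write gene lines whose TSS round-trips through :func:`read_gtf_tss`."""
    with open(path, "w") as fh:
        for row in genes.genes.itertuples(index=False):
            if row.strand == "+":
                start, end = row.tss + 1, row.tss + gene_length
            else:
                start, end = max(1, row.tss + 2 - gene_length), row.tss + 1
            fh.write(
                f"{row.chrom}\tborderquant\tgene\t{start}\t{end}\t.\t{row.strand}\t.\t"
                f'gene_id "{row.gene_id}";\n'
            )


def read_tss_bed(path) -> GenomeAnnotation:
    """Read a 6-column BED of TSS points (start = 0-based TSS)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: TSS BED needs 6 fields")
            rows.append((fields[3], fields[0], fields[5], int(fields[1])))
    return GenomeAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]))


def write_tss_bed(path, genes: GenomeAnnotation) -> None:
    with open(path, "w") as fh:
        for row in genes.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.tss}\t{row.tss + 1}\t{row.gene_id}\t.\t{row.strand}\n")
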