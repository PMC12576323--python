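"""LD clumping of significant variants and TSS-proximity enrichment.

Clumping greedily keeps the most significant variant and removes later
variants that are both physically close (< 250 kb by default) and in high
LD (r-squared > 0.5 by default) with a kept one, so one association signal
is reported once.  r-squared is the squared Pearson correlation of dosage
vectors, computed in-sample by default or against a supplied reference
panel.

TSS analysis assigns each SNP the signed distance to its nearest
transcription start site — negative upstream of the gene, positive
downstream, on either strand — and tests whether identified SNPs
concentrate within +/-250 kb of a TSS more than randomly sampled reference
SNPs, by a continuity-corrected (Yates) chi-squared test on the 2x2
within/beyond table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .matched_data import DosageMatrix, VariantRecord

__all__ = [
    "TssAnnotation",
    "ContingencyTable2x2",
    "read_tss_bed",
    "pairwise_r2",
    "ld_clump",
    "nearest_tss",
    "tss_enrichment",
    "enrichment_table",
    "sample_reference_snps",
]


@dataclass
class TssAnnotation:
    """Per-gene transcription start sites (1-based positions)."""

    chrom: list[str]
    pos: list[int]
    strand: list[str]
    gene: list[str]

    def __post_init__(self) -> None:
        n = len(self.gene)
        if not (len(self.chrom) == len(self.pos) == len(self.strand) == n):
            raise ValueError("annotation columns have unequal lengths")
        if any(p < 1 for p in self.pos):
            raise ValueError("TSS positions must be >= 1")
        if any(s not in {"+", "-"} for s in self.strand):
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.gene)


@dataclass
class ContingencyTable2x2:
    """Counts: rows = (identified, reference) SNPs, cols = (within, beyond) window."""

    a: int  # identified, within
    b: int  # identified, beyond
    c: int  # reference, within
    d: int  # reference, beyond

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def read_tss_bed(path) -> TssAnnotation:
    """Read TSS sites from BED6 (0-based half-open).

    The TSS of a + strand gene is start+1 in 1-based coordinates; of a -
    strand gene, the end coordinate.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    pos = [
        int(r.start) + 1 if r.strand == "+" else int(r.end)
        for r in frame.itertuples()
    ]
    return TssAnnotation(
        chrom=list(frame["chrom"]), pos=pos,
        strand=list(frame["strand"]), gene=list(frame["name"]),
    )


def pairwise_r2(
    dosages: DosageMatrix, v1: int, v2: int, panel: DosageMatrix | None = None
) -> float:
    """Squared Pearson correlation of two variants' dosage vectors.

    ``panel`` substitutes an external reference genotype matrix (matched by
    variant id) for the in-sample dosages.
    """
    source = dosages if panel is None else panel
    if panel is not None:
        v1 = panel.variant_index(dosages.variants[v1].id)
        v2 = panel.variant_index(dosages.variants[v2].id)
    x, y = source.values[:, v1], source.values[:, v2]
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("r2 undefined for a variant with zero dosage variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_clump(
    results: pd.DataFrame,
    dosages: DosageMatrix,
    r2_threshold: float = 0.5,
    window: int = 250_000,
    p_column: str = "p_int",
    panel: DosageMatrix | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping of a per-variant result table.

    Rows are visited in ascending p; a row is dropped when some already
    kept variant on the same chromosome lies within ``window`` bp AND has
    r-squared above ``r2_threshold`` with it (both conditions required).
    The returned frame is a subset of the input and always contains the
    globally most significant variant.
    """
    if p_column not in results.columns:
        raise KeyError(f"results table has no column {p_column!r}")
    frame = results.dropna(subset=[p_column])
    order = frame.sort_values([p_column, "chrom", "pos"], kind="stable").index
    vindex = {v.id: j for j, v in enumerate(dosages.variants)}
    kept: list = []  # (index, chrom, pos, variant column index)
    kept_rows = []
    for idx in order:
        row = frame.loc[idx]
        vid = row["variant_id"]
        if vid not in vindex:
            raise KeyError(f"no genotype column for variant {vid!r}")
        j = vindex[vid]
        clumped = False
        for _, kchrom, kpos, kj in kept:
            if kchrom == row["chrom"] and abs(int(row["pos"]) - kpos) < window:
                if pairwise_r2(dosages, j, kj, panel=panel) > r2_threshold:
                    clumped = True
                    break
        if not clumped:
            kept.append((idx, row["chrom"], int(row["pos"]), j))
            kept_rows.append(idx)
    return results.loc[sorted(kept_rows, key=list(results.index).index)]


def nearest_tss(snp: VariantRecord, ann: TssAnnotation) -> int | None:
    """Signed distance (bp) from a SNP to its nearest TSS; None if the
    SNP's chromosome carries no annotated TSS.

    Sign convention: on the + strand distance = pos_snp - pos_tss; on the -
    strand distance = pos_tss - pos_snp, so upstream of the gene is always
    negative.  Ties in absolute distance break toward the gene listed first
    in the annotation.
    """
    best: tuple[int, int] | None = None  # (|d|, signed d)
    for chrom, pos, strand in zip(ann.chrom, ann.pos, ann.strand):
        if chrom != snp.chrom:
            continue
        d = snp.pos - pos if strand == "+" else pos - snp.pos
        if best is None or abs(d) < best[0]:
            best = (abs(d), d)
    return None if best is None else best[1]


def enrichment_table(
    identified_distances,
    reference_distances,
    window: int = 250_000,
) -> ContingencyTable2x2:
    """Build the 2x2 within/beyond table from signed TSS distances.

    Distances of None (no TSS on the chromosome) are excluded; "within"
    means absolute distance strictly below ``window``.
    """
    def split(ds):
        ds = [d for d in ds if d is not None]
        within = sum(abs(d) < window for d in ds)
        return within, len(ds) - within

    a, b = split(identified_distances)
    c, d = split(reference_distances)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def tss_enrichment(table: ContingencyTable2x2) -> tuple[float, float]:
    """Yates-corrected chi-squared test of TSS-window enrichment (1 df)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined with a zero margin")
    chi2, p, _, _ = chi2_contingency(arr, correction=True)
    return float(chi2), float(p)


def sample_reference_snps(dosages: DosageMatrix, n: int = 1000, seed: int = 0) -> np.ndarray:
    """Uniform seeded sample of ``n`` variant indices without replacement."""
    if n > dosages.n_variants:
        raise ValueError(
            f"cannot sample {n} variants from a pool of {dosages.n_variants}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(dosages.n_variants, size=n, replace=False))
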