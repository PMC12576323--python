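"""Genotype dosages and matched case-control strata.

Dosage data are per-sample expected alternative-allele counts in [0, 2]
(from genotype imputation), held as a dense sample x variant matrix.
Matched 1:1 case-control strata are grouped into cohorts (e.g. one cohort
per cancer type).  The conditional logistic likelihood for 1:1 pairs
depends on the data only through the within-stratum covariate difference
``Z_i = X_case - X_control``; :func:`build_differences` produces that
representation with the per-stratum response fixed at 1.

Two dosage formats are read:

* VCF (1-based positions) with a per-genotype ``DS`` dosage FORMAT field;
  when ``DS`` is absent, hard genotype calls are converted to 0/1/2
  alternative-allele counts.  Only biallelic records are accepted.
* A plain tab-separated dialect: first column sample id, header row of
  variant ids.  Variant ids of the form ``chrom:pos`` (optionally
  ``chrom:pos:ref:alt``) are parsed for coordinates; otherwise the
  chromosome is recorded as ``"."`` and the position as the column index
  plus one.

The strata file is tab-separated with header columns
``stratum_id  cohort  case_sample  control_sample``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "DosageMatrix",
    "MatchedCohort",
    "DifferenceData",
    "DosageValidationError",
    "StrataStructureError",
    "read_dosages",
    "read_strata",
    "compute_maf",
    "filter_common",
    "build_differences",
    "cohort_differences",
    "write_dosages_tsv",
    "write_dosages_vcf",
    "write_strata",
]

DOSAGE_TOL = 1e-6


class DosageValidationError(ValueError):
    """A dosage value lies outside [0, 2] beyond tolerance, or the file is malformed."""


class StrataStructureError(ValueError):
    """A stratum definition violates the one-case/one-control structure."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant: coordinates, alleles and (optionally) its MAF."""

    chrom: str
    pos: int
    id: str
    ref: str = "."
    alt: str = "."
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF must lie in [0, 0.5], got {self.maf}")


@dataclass
class DosageMatrix:
    """Dense sample x variant dosage grid with every value in [0, 2]."""

    samples: list[str]
    variants: list[VariantRecord]
    values: np.ndarray  # shape (n_samples, n_variants)
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        vids = [v.id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValueError("variant ids are not unique")
        if self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < -DOSAGE_TOL or hi > 2.0 + DOSAGE_TOL:
                raise DosageValidationError(
                    f"dosage outside [0, 2]: observed range [{lo}, {hi}]"
                )
            # tolerate float fuzz at the boundaries only
            np.clip(self.values, 0.0, 2.0, out=self.values)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_rows(self, names: list[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in dosage matrix") from None

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not present")

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]


@dataclass
class MatchedCohort:
    """One cohort's ordered 1:1 matched strata: (stratum_id, case, control)."""

    label: str
    strata: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, case, control in self.strata:
            if case == control:
                raise StrataStructureError(
                    f"stratum {sid!r} in cohort {self.label!r} pairs a sample with itself"
                )
            for s in (case, control):
                if s in seen:
                    raise StrataStructureError(
                        f"sample {s!r} appears in more than one stratum of cohort {self.label!r}"
                    )
                seen.add(s)

    @property
    def n0(self) -> int:
        return len(self.strata)

    @property
    def case_samples(self) -> list[str]:
        return [s[1] for s in self.strata]

    @property
    def control_samples(self) -> list[str]:
        return [s[2] for s in self.strata]

    def swapped(self, flip: np.ndarray) -> "MatchedCohort":
        """Return a copy with case/control labels exchanged where ``flip`` is True."""
        flip = np.asarray(flip, dtype=bool)
        if flip.shape != (self.n0,):
            raise ValueError("flip indicator length must equal the number of strata")
        strata = [
            (sid, ctrl, case) if f else (sid, case, ctrl)
            for (sid, case, ctrl), f in zip(self.strata, flip)
        ]
        return MatchedCohort(self.label, strata)


@dataclass
class DifferenceData:
    """Per-stratum case-minus-control covariate differences with response fixed at 1."""

    z: np.ndarray  # shape (n0, p)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim == 1:
            self.z = self.z[:, None]
        elif self.z.ndim != 2:
            raise ValueError("z must be a vector or 2-D matrix")

    @property
    def n0(self) -> int:
        return self.z.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    @property
    def ystar(self) -> np.ndarray:
        return np.ones(self.n0)


_COORD_ID = re.compile(r"^(?P<chrom>[\w.]+):(?P<pos>\d+)(?::(?P<ref>[ACGTN]+):(?P<alt>[ACGTN]+))?$")


def _variant_from_id(vid: str, fallback_pos: int) -> VariantRecord:
    m = _COORD_ID.match(vid)
    if m:
        return VariantRecord(
            chrom=m["chrom"],
            pos=int(m["pos"]),
            id=vid,
            ref=m["ref"] or ".",
            alt=m["alt"] or ".",
        )
    return VariantRecord(chrom=".", pos=fallback_pos, id=vid)


def read_dosages(path: str | Path, format: str | None = None) -> DosageMatrix:
    """Read a dosage matrix from VCF (``DS`` FORMAT field) or the TSV dialect.

    ``format`` is ``"vcf"`` or ``"tsv"``; when None it is inferred from the
    file suffix.  Dosages outside [0, 2] beyond a 1e-6 tolerance raise
    :class:`DosageValidationError`.
    """
    path = Path(path)
    if format is None:
        suffixes = {s.lower() for s in path.suffixes}
        format = "vcf" if ".vcf" in suffixes else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dosage format {format!r}")


def _read_tsv(path: Path) -> DosageMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DosageValidationError(f"malformed dosage TSV {path}: {exc}") from exc
    if frame.isna().to_numpy().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise DosageValidationError(
            f"missing dosage value in row for sample {bad!r}; missing dosages are rejected"
        )
    variants = [_variant_from_id(str(c), j + 1) for j, c in enumerate(frame.columns)]
    return DosageMatrix(
        samples=[str(s) for s in frame.index],
        variants=variants,
        values=frame.to_numpy(dtype=float),
    )


def _read_vcf(path: Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise DosageValidationError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} not supported; "
                "split into biallelic records first"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(
            VariantRecord(chrom=rec.CHROM, pos=rec.POS, id=vid, ref=rec.REF, alt=rec.ALT[0])
        )
        ds = rec.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            # fall back to hard genotypes: count alternative alleles
            gts = np.asarray(rec.genotypes)[:, :2]
            if (gts < 0).any():
                raise DosageValidationError(
                    f"missing genotype at {rec.CHROM}:{rec.POS}; missing dosages are rejected"
                )
            col = gts.sum(axis=1).astype(float)
        if np.isnan(col).any():
            raise DosageValidationError(
                f"missing dosage at {rec.CHROM}:{rec.POS}; missing dosages are rejected"
            )
        if col.min() < -DOSAGE_TOL or col.max() > 2.0 + DOSAGE_TOL:
            raise DosageValidationError(
                f"dosage outside [0, 2] at {rec.CHROM}:{rec.POS}: "
                f"range [{col.min()}, {col.max()}]"
            )
        columns.append(col)
    values = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return DosageMatrix(samples=samples, variants=variants, values=values)


def read_strata(path: str | Path, dosages: DosageMatrix) -> list[MatchedCohort]:
    """Read the strata table and partition it into one :class:`MatchedCohort` per label.

    Every referenced sample must exist in ``dosages``; strata are sorted by
    stratum id within each cohort and cohorts are returned sorted by label.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["stratum_id", "cohort", "case_sample", "control_sample"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise StrataStructureError(f"strata file missing columns {missing}")
    if frame[required].isna().to_numpy().any():
        raise StrataStructureError("strata file contains empty fields")
    for s in pd.concat([frame["case_sample"], frame["control_sample"]]):
        if s not in dosages._sample_index:
            raise KeyError(f"strata file references unknown sample {s!r}")
    cohorts = []
    for label, grp in frame.groupby("cohort", sort=True):
        grp = grp.sort_values("stratum_id", kind="stable")
        strata = list(zip(grp["stratum_id"], grp["case_sample"], grp["control_sample"]))
        cohorts.append(MatchedCohort(label=str(label), strata=strata))
    return cohorts


def compute_maf(dosages: DosageMatrix, variant: int) -> float:
    """Minor-allele frequency of one variant: min(f, 1-f) with f = sum(dosage)/(2n)."""
    if dosages.n_samples == 0:
        raise ValueError("cannot compute MAF with no samples")
    f = float(dosages.values[:, variant].sum()) / (2.0 * dosages.n_samples)
    return min(f, 1.0 - f)


def filter_common(dosages: DosageMatrix, threshold: float = 0.05) -> DosageMatrix:
    """Retain variants with MAF strictly greater than ``threshold``, order preserved."""
    keep = [j for j in range(dosages.n_variants) if compute_maf(dosages, j) > threshold]
    variants = [dosages.variants[j] for j in keep]
    return DosageMatrix(
        samples=list(dosages.samples),
        variants=variants,
        values=dosages.values[:, keep].copy(),
    )


def build_differences(
    cohort: MatchedCohort, dosages: DosageMatrix, variant: int | None = None
) -> DifferenceData:
    """Case-minus-control dosage differences for one cohort.

    With ``variant`` given, z has one column for that variant; otherwise all
    variants are included as columns.
    """
    z = cohort_differences(cohort, dosages)
    if variant is not None:
        z = z[:, [variant]]
    return DifferenceData(z=z)


def cohort_differences(cohort: MatchedCohort, dosages: DosageMatrix) -> np.ndarray:
    """All-variant difference matrix (n0 x n_variants) for one cohort."""
    case_rows = dosages.sample_rows(cohort.case_samples)
    ctrl_rows = dosages.sample_rows(cohort.control_samples)
    return dosages.values[case_rows, :] - dosages.values[ctrl_rows, :]


def write_dosages_tsv(dosages: DosageMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        dosages.values, index=pd.Index(dosages.samples, name="sample"),
        columns=[v.id for v in dosages.variants],
    )
    frame.to_csv(path, sep="\t", float_format="%.6f")


def write_dosages_vcf(dosages: DosageMatrix, path: str | Path) -> None:
    """Write a minimal VCF with a DS FORMAT field (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternative allele dosage">\n')
        chroms = {v.chrom for v in dosages.variants}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dosages.samples) + "\n")
        order = sorted(
            range(dosages.n_variants),
            key=lambda j: (dosages.variants[j].chrom, dosages.variants[j].pos),
        )
        for j in order:
            v = dosages.variants[j]
            ref = v.ref if v.ref != "." else "A"
            alt = v.alt if v.alt != "." else "C"
            ds = "\t".join(f"{x:.6f}" for x in dosages.values[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{ref}\t{alt}\t.\t.\t.\tDS\t{ds}\n")


def write_strata(cohorts: list[MatchedCohort], path: str | Path) -> None:
    rows = [
        {"stratum_id": sid, "cohort": c.label, "case_sample": case, "control_sample": ctrl}
        for c in cohorts
        for sid, case, ctrl in c.strata
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
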