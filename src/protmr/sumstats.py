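"""Reading, writing and harmonizing GWAS-style summary statistics.

The on-disk formats are plain text: summary statistics as a delimited table
with canonical columns ``SNP, CHR, BP, A1, A2, EAF, BETA, SE, P, N`` (A1 is the
effect allele; a ``column_map`` translates other headers), LD as a square
numeric matrix with one header row of variant IDs, and gene annotations as a
``gene_id, CHR, START, END`` table. Positions are 1-based; intervals are
closed.

Harmonization aligns an outcome dataset onto the exposure's effect-allele
convention: swapped alleles flip the outcome beta's sign (and replace eaf by
1-eaf), complement-strand codings are accepted for non-palindromic variants,
and strand-ambiguous palindromic variants (A/T, C/G) are dropped outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MRInput

logger = logging.getLogger(__name__)

__all__ = [
    "SNPRecord",
    "SummaryStatSet",
    "LDMatrix",
    "GeneAnnotation",
    "FormatError",
    "IntegrityError",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_annotation",
    "is_palindromic",
    "harmonize_pair",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]


class FormatError(ValueError):
    """Malformed input file (missing columns, non-square matrix, ...)."""


class IntegrityError(ValueError):
    """Input file is well-formed but internally inconsistent."""


@dataclass
class SNPRecord:
    """One variant's association summary for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"{self.variant_id}: p must be in (0, 1]")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1]")
        if not self.n > 0:
            raise ValueError(f"{self.variant_id}: n must be > 0")


@dataclass
class SummaryStatSet:
    """A keyed collection of SNPRecords for one trait."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: dict[str, SNPRecord]
    n_cases: int | None = None
    n_controls: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.variant_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
             np.nan if r.eaf is None else r.eaf, r.beta, r.se, r.pvalue, r.n)
            for r in self
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


@dataclass
class LDMatrix:
    """Pairwise allelic correlations (r, not r^2) in a fixed variant order."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant list")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("LD matrix diagonal must be 1")

    def submatrix(self, variant_ids: list[str]) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise IntegrityError(f"variants missing from LD matrix: {missing}")
        idx = np.array([index[v] for v in variant_ids], dtype=int)
        return self.r[np.ix_(idx, idx)]


@dataclass
class GeneAnnotation:
    """A gene's span (1-based, inclusive), anchoring its cis window."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryStatSet:
    """Read a delimited summary-statistics table into a SummaryStatSet.

    ``column_map`` maps canonical names (SNP, CHR, BP, A1, A2, EAF, BETA, SE,
    P, N) to the file's actual headers; unmapped canonical names are looked up
    verbatim. EAF may be absent entirely. Rows with non-positive SE or with p
    outside (0, 1] are dropped and counted (``n_dropped``, also logged).
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    colmap.update(column_map or {})
    for canon in CANONICAL_COLUMNS:
        if canon == "EAF":
            continue
        if colmap[canon] not in df.columns:
            raise FormatError(f"missing required column {colmap[canon]!r} (for {canon})")
    has_eaf = colmap["EAF"] in df.columns

    ids = df[colmap["SNP"]].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise IntegrityError(f"duplicate variant IDs: {dup}")

    se = pd.to_numeric(df[colmap["SE"]], errors="coerce")
    p = pd.to_numeric(df[colmap["P"]], errors="coerce")
    ok = (se > 0) & (p > 0) & (p <= 1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)
    df = df[ok]

    records: dict[str, SNPRecord] = {}
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        eaf = float(row[colmap["EAF"]]) if has_eaf and pd.notna(row[colmap["EAF"]]) else None
        rec = SNPRecord(
            variant_id=str(row[colmap["SNP"]]),
            chrom=str(row[colmap["CHR"]]),
            pos=int(row[colmap["BP"]]),
            effect_allele=str(row[colmap["A1"]]),
            other_allele=str(row[colmap["A2"]]),
            eaf=eaf,
            beta=float(row[colmap["BETA"]]),
            se=float(row[colmap["SE"]]),
            pvalue=float(row[colmap["P"]]),
            n=float(row[colmap["N"]]),
        )
        records[rec.variant_id] = rec
    return SummaryStatSet(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        records=records,
        n_cases=n_cases,
        n_controls=n_controls,
        n_dropped=n_dropped,
    )


def write_sumstats(sset: SummaryStatSet, path) -> None:
    """Write a SummaryStatSet as canonical tab-delimited text (full precision)."""
    sset.to_frame().to_csv(path, sep="\t", index=False)


def read_ld_matrix(path, ids: list[str] | None = None) -> LDMatrix:
    """Read a plain-text LD matrix (one header row of variant IDs).

    The matrix must be square; asymmetry up to 1e-6 is repaired by averaging
    with the transpose, larger asymmetry is an integrity error. The diagonal
    is forced to exactly 1. If ``ids`` is given, the matrix is reordered to
    that variant order (an error if the sets differ).
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    variant_ids = [str(c) for c in df.columns]
    m = np.asarray(df.to_numpy(), dtype=float)
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"LD matrix is {m.shape[0]}x{m.shape[1]}, expected square")
    asym = float(np.max(np.abs(m - m.T))) if m.size else 0.0
    if asym > 1e-6:
        raise IntegrityError(f"LD matrix asymmetry {asym:.3g} exceeds 1e-6")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    ld = LDMatrix(variant_ids, m)
    if ids is not None:
        if set(ids) != set(variant_ids):
            raise IntegrityError("LD matrix variants do not match expected IDs")
        ld = LDMatrix(list(ids), ld.submatrix(list(ids)))
    return ld


def write_ld_matrix(ld: LDMatrix, path, float_format: str = "%.6f") -> None:
    """Six decimals by default: ample for correlations, keeps files compact."""
    pd.DataFrame(ld.r, columns=ld.variant_ids).to_csv(
        path, sep="\t", index=False, float_format=float_format)


def read_gene_annotation(path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("gene_id", "CHR", "START", "END"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    return {
        str(r.gene_id): GeneAnnotation(str(r.gene_id), str(r.CHR), int(r.START), int(r.END))
        for r in df.itertuples(index=False)
    }


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _match_orientation(exp: SNPRecord, out: SNPRecord) -> str | None:
    """'same', 'swap', or None if the allele codings cannot be reconciled."""
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return "same"
    if o == e[::-1]:
        return "swap"
    oc = (COMPLEMENT[o[0]], COMPLEMENT[o[1]])
    if oc == e:
        return "same"
    if oc == e[::-1]:
        return "swap"
    return None


def harmonize_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    drop_palindromic: bool = True,
) -> MRInput:
    """Align outcome effects to the exposure's effect-allele convention.

    Swapped codings flip the outcome beta sign (eaf -> 1-eaf); complement-
    strand codings are accepted for non-palindromic variants; palindromic
    variants are dropped when ``drop_palindromic``; irreconcilable codings are
    dropped. Per-reason drop counts are recorded on the returned MRInput.
    """
    shared = [v for v in exposure.records if v in outcome.records]
    if not shared:
        raise IntegrityError("no shared variants between exposure and outcome")
    drops = {"palindromic": 0, "allele_mismatch": 0}
    ids, bx, sx, by, sy = [], [], [], [], []
    n_exp, n_out = [], []
    for v in shared:
        e, o = exposure.records[v], outcome.records[v]
        if drop_palindromic and is_palindromic(e.effect_allele, e.other_allele):
            drops["palindromic"] += 1
            continue
        orient = _match_orientation(e, o)
        if orient is None:
            drops["allele_mismatch"] += 1
            continue
        beta_out = o.beta if orient == "same" else -o.beta
        ids.append(v)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(beta_out)
        sy.append(o.se)
        n_exp.append(e.n)
        n_out.append(o.n)
    if not ids:
        raise IntegrityError("all shared variants were dropped during harmonization")
    return MRInput(
        protein_id=exposure.trait_id,
        variant_ids=ids,
        bx=np.array(bx),
        sx=np.array(sx),
        by=np.array(by),
        sy=np.array(sy),
        n_exposure=int(round(float(np.median(n_exp)))),
        n_outcome=int(round(float(np.median(n_out)))),
        drop_counts=drops,
    )
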