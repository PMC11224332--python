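"""Cis-instrument selection for protein exposures.

A variant qualifies as an instrument when it lies in the gene's cis window
(default +/- 10 Mb), reaches genome-wide significance (p < 5e-8) and is strong
(F > 10, with F approximated by the squared z-score (beta/se)^2, the standard
single-SNP strength proxy). Surviving instruments are greedily LD-clumped
(default r^2 < 0.2 within a 10,000 kb window; the strict replication setting
uses r^2 < 0.001). Variants significantly associated with more than five
proteins are excluded as likely pleiotropic, and an offline trait-association
table can flag — not remove — instruments associated with potential
confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sumstats import GeneAnnotation, IntegrityError, LDMatrix, SNPRecord, SummaryStatSet

__all__ = [
    "Instrument",
    "f_statistic",
    "select_cis_instruments",
    "greedy_clump",
    "cross_protein_filter",
    "confounder_filter",
]


@dataclass
class Instrument:
    record: SNPRecord
    f_stat: float
    selected: bool
    drop_reason: str = ""
    confounder_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.selected and self.drop_reason:
            raise ValueError("selected instrument cannot carry a drop_reason")


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument strength, F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def select_cis_instruments(
    exposure: SummaryStatSet,
    gene: GeneAnnotation,
    window_bp: int = 10_000_000,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
) -> list[Instrument]:
    """Classify every exposure variant as a selected cis instrument or not.

    Selected iff on the gene's chromosome within [start - window_bp,
    end + window_bp] (closed interval), p < p_threshold and F > f_threshold.
    Others carry drop_reason 'trans', 'not_significant' or 'weak'.
    """
    if len(exposure) == 0:
        raise ValueError("empty exposure set")
    out: list[Instrument] = []
    lo, hi = gene.start - window_bp, gene.end + window_bp
    for rec in exposure:
        f = f_statistic(rec.beta, rec.se)
        if rec.chrom != gene.chrom or not lo <= rec.pos <= hi:
            out.append(Instrument(rec, f, False, "trans"))
        elif not rec.pvalue < p_threshold:
            out.append(Instrument(rec, f, False, "not_significant"))
        elif not f > f_threshold:
            out.append(Instrument(rec, f, False, "weak"))
        else:
            out.append(Instrument(rec, f, True))
    return out


def greedy_clump(
    instruments: list[Instrument],
    ld: LDMatrix,
    r2_threshold: float = 0.2,
    window_kb: float = 10_000,
) -> list[Instrument]:
    """Greedy LD clumping by ascending p-value (ties by variant_id).

    The best remaining variant becomes an index SNP and removes every
    not-yet-kept candidate within ``window_kb`` of it whose r^2 with it is
    >= ``r2_threshold`` (so the kept set satisfies r^2 < threshold). Removed
    instruments are marked drop_reason='clumped' in place; the kept list is
    returned.
    """
    pool = [ins for ins in instruments if ins.selected]
    idx = {v: i for i, v in enumerate(ld.variant_ids)}
    missing = [ins.record.variant_id for ins in pool if ins.record.variant_id not in idx]
    if missing:
        raise IntegrityError(f"instruments missing from LD matrix: {missing}")
    pool.sort(key=lambda ins: (ins.record.pvalue, ins.record.variant_id))
    window_bp = window_kb * 1000.0
    kept: list[Instrument] = []
    while pool:
        index_snp = pool.pop(0)
        kept.append(index_snp)
        i = idx[index_snp.record.variant_id]
        survivors = []
        for ins in pool:
            close = abs(ins.record.pos - index_snp.record.pos) <= window_bp
            r2 = ld.r[i, idx[ins.record.variant_id]] ** 2
            if close and r2 >= r2_threshold:
                ins.selected = False
                ins.drop_reason = "clumped"
            else:
                survivors.append(ins)
        pool = survivors
    return kept


def cross_protein_filter(
    assoc: pd.DataFrame,
    max_proteins: int = 5,
    p_threshold: float = 5e-8,
) -> set[str]:
    """Variants significantly associated with more than ``max_proteins``
    distinct proteins (likely horizontally pleiotropic). ``assoc`` has columns
    variant_id, protein_id, p."""
    if assoc.empty:
        return set()
    sig = assoc[assoc["p"] < p_threshold]
    counts = sig.groupby("variant_id")["protein_id"].nunique()
    return set(counts[counts > max_proteins].index.astype(str))


def confounder_filter(
    instruments: list[Instrument],
    trait_assoc: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> list[Instrument]:
    """Annotate (never remove) instruments with confounder traits they hit.

    ``trait_assoc`` has columns variant_id, trait, p; traits with
    p < p_threshold for an instrument's variant are recorded on it. The
    screening-then-judgement usage leaves removal to the analyst.
    """
    if trait_assoc.empty:
        for ins in instruments:
            ins.confounder_traits = []
        return instruments
    sig = trait_assoc[trait_assoc["p"] < p_threshold]
    by_variant = sig.groupby("variant_id")["trait"].apply(list).to_dict()
    for ins in instruments:
        ins.confounder_traits = sorted(by_variant.get(ins.record.variant_id, []))
    return instruments
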