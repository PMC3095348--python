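"""Assemble domain hits into per-protein CRF architecture calls.

A CRF protein is defined by a CRF core domain in the N-terminal region paired
with an AP2 DNA-binding domain roughly 60 residues further C-terminal.  Clade
A members additionally carry the TEH region, an ~13-residue extension
immediately preceding the CRF core; clade B members lack it.  Proteins with
an AP2 domain but no valid CRF core pairing are ordinary (non-CRF) ERFs.  A
CRF core without any AP2 domain contradicts the family model — the CRF domain
is never observed without an AP2 domain — and is therefore flagged as an
anomaly rather than classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .motif_profile import DetectorSet, DomainHit, DomainKind, scan_all
from .seq_io import ProteinRecord


class Category(str, Enum):
    CRF_CLADE_A = "CRF_CLADE_A"
    CRF_CLADE_B = "CRF_CLADE_B"
    ERF_NON_CRF = "ERF_NON_CRF"
    UNCLASSIFIED = "UNCLASSIFIED"


CRF_CATEGORIES = frozenset({Category.CRF_CLADE_A, Category.CRF_CLADE_B})

#: Advisory flags attached to calls.
PHOS_MOTIF_PRESENT = "PHOS_MOTIF_PRESENT"
SPACER_ATYPICAL = "SPACER_ATYPICAL"
CRF_WITHOUT_AP2_ANOMALY = "CRF_WITHOUT_AP2_ANOMALY"


@dataclass(frozen=True)
class ArchitectureRules:
    """Tunable geometry of the CRF architecture.

    spacer_min/spacer_max bound the residue gap between the CRF core end and
    the AP2 start (default [20, 120] around the canonical ~60).  teh_gap_max
    is the largest tolerated gap between a TEH end and the core start
    (default 5: the TEH immediately precedes the core, with slack for
    alignment jitter).  require_crf_nterm demands the core start before the
    AP2 start.
    """

    spacer_min: int = 20
    spacer_max: int = 120
    teh_gap_max: int = 5
    require_crf_nterm: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if self.teh_gap_max < 0:
            raise ValueError("teh_gap_max must be non-negative")


@dataclass(frozen=True)
class ArchitectureCall:
    """Per-protein classification with its supporting hits and flags."""

    seq_id: str
    category: Category
    evidence: tuple[DomainHit, ...] = ()
    flags: frozenset = frozenset()

    def hit(self, kind: DomainKind) -> DomainHit | None:
        for h in self.evidence:
            if h.kind is kind:
                return h
        return None


def classify_architecture(
    seq: ProteinRecord, hits: Sequence[DomainHit], rules: ArchitectureRules
) -> ArchitectureCall:
    """Classify one protein from its domain hits.

    The best-scoring CRF-core/AP2 pair (maximal summed score; ties resolved
    toward the smallest core start, then AP2 start) with the core N-terminal
    to the AP2 and a spacer within ``[spacer_min, spacer_max]`` makes the
    protein a CRF; a TEH hit ending within ``teh_gap_max`` of the chosen core
    start assigns clade A, otherwise clade B.  An AP2 with no valid pair is a
    non-CRF ERF; a CRF core with no AP2 at all is flagged as an anomaly.
    """
    n = len(seq.residues)
    for h in hits:
        if h.seq_id != seq.id:
            raise ValueError(f"hit on {h.seq_id!r} does not belong to {seq.id!r}")
        if h.end > n:
            raise ValueError(
                f"hit [{h.start}, {h.end}) exceeds length {n} of {seq.id!r}"
            )

    cores = [h for h in hits if h.kind is DomainKind.CRF_CORE]
    ap2s = [h for h in hits if h.kind is DomainKind.AP2]
    tehs = [h for h in hits if h.kind is DomainKind.TEH]
    phoss = [h for h in hits if h.kind is DomainKind.PHOS_MOTIF]

    flags: set[str] = set()
    best_pair: tuple[DomainHit, DomainHit] | None = None
    best_key: tuple | None = None
    saw_ordered_out_of_band = False
    for c in cores:
        for a in ap2s:
            if rules.require_crf_nterm and not c.start < a.start:
                continue
            spacer = a.start - c.end
            if spacer < 0:
                continue
            if not rules.spacer_min <= spacer <= rules.spacer_max:
                saw_ordered_out_of_band = True
                continue
            key = (-(c.score + a.score), c.start, a.start)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (c, a)

    if best_pair is not None:
        core, ap2 = best_pair
        evidence: list[DomainHit] = [core, ap2]
        teh_chosen = None
        for t in sorted(tehs, key=lambda t: (-t.score, t.start)):
            if 0 <= core.start - t.end <= rules.teh_gap_max:
                teh_chosen = t
                break
        if teh_chosen is not None:
            evidence.insert(0, teh_chosen)
        category = (
            Category.CRF_CLADE_A if teh_chosen is not None else Category.CRF_CLADE_B
        )
        phos_hit = next((p for p in phoss if p.start >= ap2.end), None)
        if phos_hit is not None:
            flags.add(PHOS_MOTIF_PRESENT)
            evidence.append(phos_hit)
        return ArchitectureCall(seq.id, category, tuple(evidence), frozenset(flags))

    if saw_ordered_out_of_band:
        flags.add(SPACER_ATYPICAL)
    if ap2s:
        best_ap2 = min(ap2s, key=lambda a: (-a.score, a.start))
        return ArchitectureCall(
            seq.id, Category.ERF_NON_CRF, (best_ap2,), frozenset(flags)
        )
    if cores:
        flags.add(CRF_WITHOUT_AP2_ANOMALY)
        best_core = min(cores, key=lambda c: (-c.score, c.start))
        return ArchitectureCall(
            seq.id, Category.UNCLASSIFIED, (best_core,), frozenset(flags)
        )
    return ArchitectureCall(seq.id, Category.UNCLASSIFIED, (), frozenset(flags))


def classify_proteome(
    records: Iterable[ProteinRecord],
    detectors: DetectorSet,
    rules: ArchitectureRules | None = None,
) -> list[ArchitectureCall]:
    """Scan every record with the detector set and classify it."""
    rules = rules or ArchitectureRules()
    return [
        classify_architecture(rec, scan_all(rec, detectors), rules)
        for rec in records
    ]


def summarize_calls(calls: Sequence[ArchitectureCall]) -> dict:
    """Counts per category, the clade A:B ratio, and the phospho-motif rate.

    The A:B ratio is ``None`` (reported as NA downstream) when no clade-B
    calls exist; the phospho-motif fraction is computed over CRF calls only
    and is ``None`` when there are none.
    """
    counts = {cat: 0 for cat in Category}
    n_phos = 0
    for call in calls:
        counts[call.category] += 1
        if call.category in CRF_CATEGORIES and PHOS_MOTIF_PRESENT in call.flags:
            n_phos += 1
    n_a = counts[Category.CRF_CLADE_A]
    n_b = counts[Category.CRF_CLADE_B]
    n_crf = n_a + n_b
    return {
        "counts": {cat.value: n for cat, n in counts.items()},
        "n_crf": n_crf,
        "ab_ratio": (n_a / n_b) if n_b else None,
        "phos_motif_fraction": (n_phos / n_crf) if n_crf else None,
    }
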