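"""Labeled synthetic proteomes emulating the CRF domain architecture.

The generator writes proteins of four kinds, mixed 0.4 / 0.2 / 0.2 / 0.2 by
default (clade A CRFs are about twice as numerous as clade B within plant
genomes):

* clade A CRF — ``[N-flank][TEH 13][CRF core 40][spacer ~60][AP2 25][C-flank]``
* clade B CRF — as clade A but with a neutral random segment in the TEH slot
* non-CRF ERF — flanks around an AP2 instance only
* background — random residues

AP2 instances realize the printed degenerate consensus with wildcards drawn
uniformly; the CRF core and TEH consensus strings are themselves random draws
(their real residue content must come from user seed alignments, so the
synthetic stand-ins are labeled as such).  Domain residues are then mutated
at a per-residue substitution rate.  Roughly half of the CRF proteins carry
the SP[TV]SVL hexamer downstream of the AP2 domain.

CRF-category sequences share one layout (flank and spacer lengths drawn once
per simulation), so they double as a gap-free pseudo-alignment with exactly
known domain columns for phylogeny tests; non-CRF sequences have fully
variable lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .architecture import ArchitectureCall, Category, CRF_CATEGORIES, PHOS_MOTIF_PRESENT
from .motif_profile import AP2_CONSENSUS, DomainKind
from .seq_io import AA20, AlignedBlock, ProteinRecord

_AA = np.frombuffer(AA20.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a simulated proteome.

    Proportions must sum to 1; the default 0.4/0.2 clade mix realizes the
    canonical ~2:1 A:B abundance.  ``substitution_rate`` is the per-residue
    probability of replacing a domain residue with a uniformly random one
    (default 0.1, matching the divergence of the emitted seed alignments).
    """

    n_proteins: int = 300
    clade_a_frac: float = 0.4
    clade_b_frac: float = 0.2
    erf_only_frac: float = 0.2
    background_frac: float = 0.2
    substitution_rate: float = 0.1
    phos_motif_prob: float = 0.5
    spacer_mean: float = 60.0
    spacer_sd: float = 10.0
    teh_len: int = 13
    crf_core_len: int = 40
    ap2_template: str = AP2_CONSENSUS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.clade_a_frac,
            self.clade_b_frac,
            self.erf_only_frac,
            self.background_frac,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("category proportions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if not 0 <= self.phos_motif_prob <= 1:
            raise ValueError("phos_motif_prob must lie in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one synthetic protein."""

    seq_id: str
    category: Category
    spans: tuple[tuple[DomainKind, int, int], ...]
    phos_motif_present: bool = False

    @property
    def is_crf(self) -> bool:
        return self.category in CRF_CATEGORIES


@dataclass(frozen=True)
class SyntheticProteome:
    """Everything :func:`simulate_proteome` produces.

    ``alignment`` is the gap-free pseudo-alignment of the CRF-category
    sequences; ``domain_columns`` records the exact alignment column spans of
    the embedded TEH / CRF core / AP2 domains.
    """

    records: tuple[ProteinRecord, ...]
    labels: tuple[TruthLabel, ...]
    alignment: AlignedBlock | None
    domain_columns: tuple[tuple[DomainKind, int, int], ...]
    core_consensus: str
    teh_consensus: str
    seed_alignments: Mapping[str, AlignedBlock]
    config: SyntheticConfig


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_AA, size=n).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, s: str, rate: float) -> str:
    if rate <= 0 or not s:
        return s
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    arr[mask] = rng.choice(_AA, size=int(mask.sum()))
    return arr.tobytes().decode("ascii")


def _diverge_rows(
    rng: np.random.Generator, consensus: str, n_rows: int, divergence: float, prefix: str
) -> AlignedBlock:
    rows = tuple(
        (f"{prefix}{i + 1}", _mutate(rng, consensus, divergence))
        for i in range(n_rows)
    )
    return AlignedBlock(rows)


def make_seed_domains(
    rng_seed: int,
    *,
    core_len: int = 40,
    teh_len: int = 13,
    n_rows: int = 8,
    divergence: float = 0.1,
) -> tuple[str, str, dict[str, AlignedBlock]]:
    """Synthetic stand-ins for the CRF core and TEH seed material.

    Draws a random core and TEH consensus and emits gapless 8-row seed
    alignments at 10% divergence from each; deterministic per seed.  These
    stand in for curated domain alignments, which users supply for real data.
    """
    rng = np.random.default_rng(rng_seed)
    core = _random_residues(rng, core_len)
    teh = _random_residues(rng, teh_len)
    seeds = {
        "CRF_CORE": _diverge_rows(rng, core, n_rows, divergence, "core_seed_"),
        "TEH": _diverge_rows(rng, teh, n_rows, divergence, "teh_seed_"),
    }
    return core, teh, seeds


def _template_length(template: str) -> int:
    n = 0
    i = 0
    while i < len(template):
        if template[i] == "[":
            i = template.index("]", i) + 1
        else:
            i += 1
        n += 1
    return n


def _instantiate_ap2(rng: np.random.Generator, template: str) -> str:
    out = []
    i = 0
    while i < len(template):
        ch = template[i]
        if ch == "*":
            out.append(chr(_AA[rng.integers(0, 20)]))
            i += 1
        elif ch == "[":
            j = template.index("]", i)
            members = template[i + 1 : j]
            out.append(members[rng.integers(0, len(members))])
            i = j + 1
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def simulate_proteome(cfg: SyntheticConfig) -> SyntheticProteome:
    """Generate a labeled proteome under the configured study conditions.

    CRF sequences within one simulation share flank and spacer lengths (one
    draw per run) so they form a gap-free pseudo-alignment with known domain
    columns; a CRF core is never emitted without an AP2 domain.  Domain
    residues (TEH, core, AP2) are mutated at ``substitution_rate``; the
    SP[TV]SVL hexamer, when present, is embedded exactly.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    core_cons, teh_cons, seeds = make_seed_domains(
        cfg.rng_seed, core_len=cfg.crf_core_len, teh_len=cfg.teh_len
    )

    # shared CRF layout for this run
    nflank = int(rng.integers(10, 81))
    spacer = max(20, int(round(rng.normal(cfg.spacer_mean, cfg.spacer_sd))))
    cflank = int(rng.integers(10, 81))
    ap2_len = _template_length(cfg.ap2_template)
    teh_span = (nflank, nflank + cfg.teh_len)
    core_span = (teh_span[1], teh_span[1] + cfg.crf_core_len)
    ap2_span = (core_span[1] + spacer, core_span[1] + spacer + ap2_len)
    domain_columns = (
        (DomainKind.TEH, *teh_span),
        (DomainKind.CRF_CORE, *core_span),
        (DomainKind.AP2, *ap2_span),
    )

    fracs = [
        cfg.clade_a_frac,
        cfg.clade_b_frac,
        cfg.erf_only_frac,
        cfg.background_frac,
    ]
    cats = rng.choice(4, size=cfg.n_proteins, p=fracs)
    categories = (
        Category.CRF_CLADE_A,
        Category.CRF_CLADE_B,
        Category.ERF_NON_CRF,
        Category.UNCLASSIFIED,
    )

    records: list[ProteinRecord] = []
    labels: list[TruthLabel] = []
    aln_rows: list[tuple[str, str]] = []
    width = len(str(cfg.n_proteins))
    for k, cat_idx in enumerate(cats):
        seq_id = f"P{k + 1:0{width}d}"
        category = categories[int(cat_idx)]
        if category in CRF_CATEGORIES:
            teh_seg = (
                _mutate(rng, teh_cons, cfg.substitution_rate)
                if category is Category.CRF_CLADE_A
                else _random_residues(rng, cfg.teh_len)
            )
            core_seg = _mutate(rng, core_cons, cfg.substitution_rate)
            ap2_seg = _mutate(
                rng, _instantiate_ap2(rng, cfg.ap2_template), cfg.substitution_rate
            )
            cflank_seg = _random_residues(rng, cflank)
            phos = bool(rng.random() < cfg.phos_motif_prob) and cflank >= 6
            phos_span = None
            if phos:
                motif = "SP" + ("TV"[rng.integers(0, 2)]) + "SVL"
                off = int(rng.integers(0, cflank - 6 + 1))
                cflank_seg = cflank_seg[:off] + motif + cflank_seg[off + 6 :]
                phos_start = ap2_span[1] + off
                phos_span = (DomainKind.PHOS_MOTIF, phos_start, phos_start + 6)
            residues = (
                _random_residues(rng, nflank)
                + teh_seg
                + core_seg
                + _random_residues(rng, spacer)
                + ap2_seg
                + cflank_seg
            )
            spans = []
            if category is Category.CRF_CLADE_A:
                spans.append(domain_columns[0])
            spans.extend(domain_columns[1:])
            if phos_span:
                spans.append(phos_span)
            records.append(ProteinRecord(id=seq_id, residues=residues))
            labels.append(
                TruthLabel(seq_id, category, tuple(spans), phos_motif_present=phos)
            )
            aln_rows.append((seq_id, residues))
        elif category is Category.ERF_NON_CRF:
            nf = int(rng.integers(10, 81))
            cf = int(rng.integers(10, 81))
            ap2_seg = _mutate(
                rng, _instantiate_ap2(rng, cfg.ap2_template), cfg.substitution_rate
            )
            residues = (
                _random_residues(rng, nf) + ap2_seg + _random_residues(rng, cf)
            )
            records.append(ProteinRecord(id=seq_id, residues=residues))
            labels.append(
                TruthLabel(
                    seq_id,
                    category,
                    ((DomainKind.AP2, nf, nf + len(ap2_seg)),),
                )
            )
        else:
            length = int(rng.integers(150, 351))
            records.append(
                ProteinRecord(id=seq_id, residues=_random_residues(rng, length))
            )
            labels.append(TruthLabel(seq_id, category, ()))

    alignment = AlignedBlock(tuple(aln_rows)) if aln_rows else None
    return SyntheticProteome(
        records=tuple(records),
        labels=tuple(labels),
        alignment=alignment,
        domain_columns=domain_columns,
        core_consensus=core_cons,
        teh_consensus=teh_cons,
        seed_alignments=seeds,
        config=cfg,
    )


@dataclass(frozen=True)
class EvaluationSummary:
    """Classifier performance against generator truth."""

    confusion: dict
    sensitivity: float
    specificity: float
    clade_accuracy: float

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_calls(
    calls: list[ArchitectureCall], truth: list[TruthLabel]
) -> EvaluationSummary:
    """Confusion matrix plus CRF sensitivity/specificity and clade accuracy.

    Sensitivity and specificity are for the binary "is CRF" decision (either
    clade); clade accuracy is the fraction of true CRF proteins whose called
    category equals the true clade (missed CRFs count as errors).
    """
    call_by_id = {c.seq_id: c for c in calls}
    truth_by_id = {t.seq_id: t for t in truth}
    if set(call_by_id) != set(truth_by_id):
        raise ValueError("call and truth id sets differ")
    confusion: dict[str, dict[str, int]] = {
        t.value: {c.value: 0 for c in Category} for t in Category
    }
    tp = fn = fp = tn = 0
    clade_correct = 0
    n_true_crf = 0
    for sid, t in truth_by_id.items():
        c = call_by_id[sid]
        confusion[t.category.value][c.category.value] += 1
        called_crf = c.category in CRF_CATEGORIES
        if t.is_crf:
            n_true_crf += 1
            tp += called_crf
            fn += not called_crf
            clade_correct += c.category == t.category
        else:
            fp += called_crf
            tn += not called_crf
    return EvaluationSummary(
        confusion=confusion,
        sensitivity=tp / n_true_crf if n_true_crf else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        clade_accuracy=clade_correct / n_true_crf if n_true_crf else float("nan"),
    )
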