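"""Motif models and scanners for CRF protein annotation.

Two motif representations are used side by side, mirroring how the CRF/ERF
literature describes its signatures:

* :class:`DegeneratePattern` — an exact consensus with ``*`` wildcards,
  bracketed residue sets (``[TV]``), and optionally a block of residues that
  must match regardless of the mismatch allowance.  The AP2/ERF DNA-binding
  core ``AAEIRD**RR*R*WLGT*DTAEEAA`` (with WLG strictly required for DNA
  binding) and the C-terminal phosphorylation motif ``SP[TV]SVL`` are both of
  this kind.
* :class:`ProfileModel` — a per-position log-odds scoring matrix built from a
  seed alignment, used for the CRF core domain and the clade-A TEH region,
  whose residue content varies across land plants and is supplied by the user
  as a seed alignment rather than hard-coded.

Scores are in bits (log base 2).  Pattern hits score the negated mismatch
count so that "higher is better" holds uniformly across hit kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import AA20, AlignedBlock, GAP, ProteinRecord

#: AP2/ERF DNA-binding core consensus for CRF proteins; ``*`` marks
#: non-specifically conserved positions, WLG is absolutely required.
AP2_CONSENSUS = "AAEIRD**RR*R*WLGT*DTAEEAA"
AP2_REQUIRED = "WLG"

#: ERF-subfamily signature at the start of the AP2 core (GCC-box binding)
#: versus the CBF/DREB signature (DRE/CRT binding).
ERF_SIGNATURE = "AAEIRD"
DREB_SIGNATURE = "VAEIRE"

#: Putative MAP-kinase/casein-kinase phosphorylation hexamer.
PHOS_CONSENSUS = "SP[TV]SVL"

#: Default mismatch budget for the AP2 degenerate pattern.
DEFAULT_AP2_MISMATCHES = 2

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


class DomainKind(str, Enum):
    """The domain/motif kinds the toolkit locates."""

    TEH = "TEH"
    CRF_CORE = "CRF_CORE"
    AP2 = "AP2"
    PHOS_MOTIF = "PHOS_MOTIF"


@dataclass(frozen=True)
class DomainHit:
    """A located, scored domain occurrence (0-based half-open coordinates).

    ``erf_type`` is set on AP2 hits only: True when the first six window
    residues are at least as close to the ERF signature AAEIRD as to the
    CBF/DREB signature VAEIRE (ties count as ERF-type).
    """

    seq_id: str
    kind: DomainKind
    start: int
    end: int
    score: float
    erf_type: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid hit span [{self.start}, {self.end}) on {self.seq_id!r}"
            )


@dataclass(frozen=True)
class DegeneratePattern:
    """Exact degenerate consensus: fixed residues, residue sets, wildcards.

    ``positions[i]`` is ``None`` for a wildcard, otherwise a frozenset of
    admissible residues.  ``required_idx`` positions must match exactly no
    matter the mismatch budget.
    """

    positions: tuple[frozenset | None, ...]
    required_idx: frozenset
    label: DomainKind

    def __post_init__(self) -> None:
        if not any(p is not None for p in self.positions):
            raise ValueError("pattern must have at least one non-wildcard position")
        if not set(self.required_idx) <= set(range(len(self.positions))):
            raise ValueError("required_idx outside pattern range")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_wildcards(self) -> int:
        return sum(p is None for p in self.positions)

    @property
    def n_optional_fixed(self) -> int:
        """Non-wildcard positions not covered by the required block."""
        return sum(
            p is not None and i not in self.required_idx
            for i, p in enumerate(self.positions)
        )


def compile_pattern(
    consensus: str, required: str, label: DomainKind
) -> DegeneratePattern:
    """Compile a consensus string into a :class:`DegeneratePattern`.

    ``*`` is a wildcard; ``[TV]`` admits either residue.  ``required`` names a
    contiguous block of fixed residues that must match exactly; its first
    occurrence among the fixed single-residue positions is marked.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    positions: list[frozenset | None] = []
    singles: list[str | None] = []  # single fixed residue per position, else None
    i = 0
    while i < len(consensus):
        ch = consensus[i]
        if ch == "*":
            positions.append(None)
            singles.append(None)
            i += 1
        elif ch == "[":
            j = consensus.index("]", i)
            members = consensus[i + 1 : j]
            if not members:
                raise ValueError("empty residue set in consensus")
            positions.append(frozenset(members))
            singles.append(None)
            i = j + 1
        else:
            positions.append(frozenset(ch))
            singles.append(ch)
            i += 1

    required_idx: frozenset = frozenset()
    if required:
        found = None
        for start in range(len(positions) - len(required) + 1):
            if all(
                singles[start + k] == required[k] for k in range(len(required))
            ):
                found = start
                break
        if found is None:
            raise ValueError(
                f"required block {required!r} does not occur among the fixed "
                f"positions of {consensus!r}"
            )
        required_idx = frozenset(range(found, found + len(required)))
    return DegeneratePattern(tuple(positions), required_idx, label)


def scan_pattern(
    seq: ProteinRecord, pattern: DegeneratePattern, max_mismatches: int
) -> list[DomainHit]:
    """Report every window matching the pattern within the mismatch budget.

    Required positions must match exactly; mismatches at the remaining fixed
    or set positions are counted and windows with count ≤ ``max_mismatches``
    are reported, sorted by start, overlaps allowed.  The hit score is the
    negated mismatch count.  ``X`` in the sequence matches only wildcards.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be non-negative")
    if max_mismatches >= pattern.n_optional_fixed and pattern.n_optional_fixed > 0:
        raise ValueError(
            "max_mismatches must be smaller than the number of optional fixed positions"
        )
    L = len(pattern)
    n = len(seq.residues)
    if n < L:
        return []
    n_win = n - L + 1
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    ok_required = np.ones(n_win, dtype=bool)
    mismatches = np.zeros(n_win, dtype=np.int32)
    for p, allowed in enumerate(pattern.positions):
        if allowed is None:
            continue
        codes = np.frombuffer("".join(sorted(allowed)).encode("ascii"), dtype=np.uint8)
        match = np.isin(arr[p : p + n_win], codes)
        if p in pattern.required_idx:
            ok_required &= match
        else:
            mismatches += ~match
    good = ok_required & (mismatches <= max_mismatches)
    hits = []
    for w in np.nonzero(good)[0]:
        w = int(w)
        erf = None
        if pattern.label is DomainKind.AP2 and L >= len(ERF_SIGNATURE):
            head = seq.residues[w : w + len(ERF_SIGNATURE)]
            d_erf = sum(a != b for a, b in zip(head, ERF_SIGNATURE))
            d_dreb = sum(a != b for a, b in zip(head, DREB_SIGNATURE))
            erf = d_erf <= d_dreb
        hits.append(
            DomainHit(
                seq_id=seq.id,
                kind=pattern.label,
                start=w,
                end=w + L,
                score=-float(mismatches[w]) if pattern.n_optional_fixed else 0.0,
                erf_type=erf,
            )
        )
    return hits


@dataclass(frozen=True)
class ProfileModel:
    """Per-position log-odds scoring matrix (bits) over the 20 residues.

    ``scores`` has shape ``(length, 20)`` in :data:`~crfkit.seq_io.AA20`
    order.  ``threshold`` is the minimum window score reported by
    :func:`scan_profile`.
    """

    scores: np.ndarray
    background: np.ndarray
    pseudocount: float
    label: DomainKind
    threshold: float = -math.inf

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "background", bg)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError("scores must have shape (length, 20)")
        if bg.shape != (20,) or np.any(bg <= 0):
            raise ValueError("background must be 20 strictly positive frequencies")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        """Best attainable window score: the sum of per-column maxima."""
        return float(self.scores.max(axis=1).sum())

    def consensus(self) -> str:
        """Per-column argmax residues (ties broken by alphabetical order)."""
        return "".join(AA20[i] for i in self.scores.argmax(axis=1))

    def with_threshold(self, threshold: float) -> "ProfileModel":
        return replace(self, threshold=float(threshold))


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def _background_vector(background: Mapping[str, float] | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(background, Mapping):
        return np.array([background[aa] for aa in AA20], dtype=float)
    return np.asarray(background, dtype=float)


def build_profile(
    seed: AlignedBlock,
    pseudocount: float,
    background: Mapping[str, float] | Sequence[float] | np.ndarray,
    label: DomainKind,
) -> ProfileModel:
    """Build a log-odds profile from a seed alignment.

    Columns that are gap in more than half the rows are dropped.  For a kept
    column with residue counts ``c`` over ``n_eff`` counted rows::

        score(r) = log2((c[r] + pseudocount * bg[r]) / (n_eff + pseudocount) / bg[r])

    Gaps (and ``X``) are excluded from the counts, so ``n_eff`` varies per
    column.  A pseudocount of 0 is permitted only when every scored residue is
    observed in every kept column.
    """
    if seed.n_rows < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = _background_vector(background)
    n_rows = seed.n_rows
    cols = []
    for c in range(seed.n_cols):
        column = [res[c] for _, res in seed.rows]
        if 2 * sum(ch == GAP for ch in column) > n_rows:
            continue
        cols.append(column)
    if not cols:
        raise ValueError("every column is majority-gap; no profile can be built")
    scores = np.empty((len(cols), 20), dtype=float)
    for ci, column in enumerate(cols):
        counts = np.zeros(20)
        for ch in column:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        n_eff = counts.sum()
        if pseudocount == 0 and np.any(counts == 0):
            raise ValueError(
                "pseudocount 0 requires every residue observed in every column"
            )
        with np.errstate(divide="ignore"):
            scores[ci] = np.log2(
                (counts + pseudocount * bg) / (n_eff + pseudocount) / bg
            )
    return ProfileModel(scores=scores, background=bg, pseudocount=float(pseudocount), label=label)


def _window_scores(residues: str, profile: ProfileModel) -> np.ndarray:
    """Scores of all windows; ``X`` contributes 0 (the background expectation)."""
    L = profile.length
    n = len(residues)
    n_win = n - L + 1
    # map residues to 0..19, X (or anything else) to a zero-score row 20
    ext = np.zeros((L, 21))
    ext[:, :20] = profile.scores
    idx = np.array([_AA_INDEX.get(ch, 20) for ch in residues], dtype=np.intp)
    total = np.zeros(n_win)
    for p in range(L):
        total += ext[p, idx[p : p + n_win]]
    return total


def resolve_overlaps(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Keep the best-scoring hit among overlapping same-kind hits.

    Candidates are considered in order of decreasing score, ties broken by
    the leftmost start; a candidate overlapping an already kept hit of the
    same kind is discarded.  The result is sorted by start.
    """
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.end)):
        if any(
            k.kind == h.kind and h.start < k.end and k.start < h.end for k in kept
        ):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def scan_profile(seq: ProteinRecord, profile: ProfileModel) -> list[DomainHit]:
    """Report non-overlapping windows scoring at least ``profile.threshold``.

    A sequence shorter than the profile yields an empty list.  Overlapping
    candidate windows are resolved by :func:`resolve_overlaps`.
    """
    if len(seq.residues) < profile.length:
        return []
    totals = _window_scores(seq.residues, profile)
    candidates = [
        DomainHit(
            seq_id=seq.id,
            kind=profile.label,
            start=int(w),
            end=int(w) + profile.length,
            score=float(totals[w]),
        )
        for w in np.nonzero(totals >= profile.threshold)[0]
    ]
    return resolve_overlaps(candidates)


def calibrate_threshold(
    profile: ProfileModel, n_null: int, target_fpr: float, rng_seed: int
) -> float:
    """Empirical null-score quantile for a per-window false-positive target.

    Draws ``n_null`` i.i.d. background-distributed windows of profile length
    and returns the ``1 - target_fpr`` quantile of their scores.
    """
    if n_null < 1000:
        raise ValueError("n_null must be at least 1000")
    if not 0 < target_fpr < 1:
        raise ValueError("target_fpr must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng_seed)
    windows = rng.choice(20, size=(n_null, profile.length), p=profile.background)
    scores = profile.scores[np.arange(profile.length), windows].sum(axis=1)
    return float(np.quantile(scores, 1.0 - target_fpr))


@dataclass(frozen=True)
class DetectorSet:
    """The detectors the default CRF-annotation pipeline runs per protein."""

    ap2: DegeneratePattern
    phos: DegeneratePattern
    core_profile: ProfileModel
    teh_profile: ProfileModel
    ap2_max_mismatches: int = DEFAULT_AP2_MISMATCHES


def ap2_pattern() -> DegeneratePattern:
    """The AP2/ERF core consensus with the WLG block strictly required."""
    return compile_pattern(AP2_CONSENSUS, AP2_REQUIRED, DomainKind.AP2)


def phos_pattern() -> DegeneratePattern:
    """The SP[TV]SVL putative phosphorylation motif (exact match)."""
    return compile_pattern(PHOS_CONSENSUS, "", DomainKind.PHOS_MOTIF)


#: Default profile threshold as a fraction of the best attainable score.
#: Half the maximum keeps the null acceptance probability negligible for
#: domain-sized profiles while tolerating substantial divergence from the
#: seed consensus.
DEFAULT_THRESHOLD_FRACTION = 0.5


def default_detector_set(
    core_seed: AlignedBlock,
    teh_seed: AlignedBlock,
    *,
    pseudocount: float = 1.0,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    ap2_max_mismatches: int = DEFAULT_AP2_MISMATCHES,
) -> DetectorSet:
    """Build the standard detector set from user-supplied seed alignments.

    The CRF core and TEH profiles use a uniform background and a threshold of
    ``threshold_fraction`` times each profile's maximum attainable score.
    """
    bg = uniform_background()
    core = build_profile(core_seed, pseudocount, bg, DomainKind.CRF_CORE)
    teh = build_profile(teh_seed, pseudocount, bg, DomainKind.TEH)
    return DetectorSet(
        ap2=ap2_pattern(),
        phos=phos_pattern(),
        core_profile=core.with_threshold(threshold_fraction * core.max_score()),
        teh_profile=teh.with_threshold(threshold_fraction * teh.max_score()),
        ap2_max_mismatches=ap2_max_mismatches,
    )


def scan_all(seq: ProteinRecord, detectors: DetectorSet) -> list[DomainHit]:
    """Run every detector on one protein; hits sorted by start."""
    hits: list[DomainHit] = []
    hits += scan_pattern(seq, detectors.ap2, detectors.ap2_max_mismatches)
    hits += scan_pattern(seq, detectors.phos, 0)
    hits += scan_profile(seq, detectors.core_profile)
    hits += scan_profile(seq, detectors.teh_profile)
    return sorted(hits, key=lambda h: (h.start, h.end, h.kind.value))
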