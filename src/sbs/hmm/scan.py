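"""Domain scanning and subtype classification.

``scan_sequence`` locates non-overlapping domain envelopes with a set of
profile HMMs; ``classify_hit`` resolves each hit into canonical-CBM40,
Vibrio-type CBM40, or reject by cross-model bit-score comparison, the
score-comparison step used to discard related non-CBM40 domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ProfileHmm
from .score import forward_bits, viterbi_align

# Candidate envelopes are enumerated down to this floor and then filtered
# by the caller's reporting threshold, which makes the reported hit list
# monotone in the threshold.  Envelopes below 0 bits (odds < 1) are never
# reported.
_FLOOR_BITS = 0.0


@dataclass
class DomainHit:
    sequence_id: str
    start: int                       # 0-based half-open envelope
    end: int
    model_name: str
    bit_score: float
    per_model_scores: dict[str, float] = field(default_factory=dict)

    @property
    def envelope(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TypeCall:
    hit: DomainHit
    label: str                       # canonical | vibrio | reject
    margin_bits: float
    tie: bool = False


def _candidate_envelopes(
    model: ProfileHmm, sequence: str, lo: int, hi: int, out: list[tuple[int, int, float]]
) -> None:
    """Recursively split the sequence around each confident envelope."""
    if hi - lo < 1:
        return
    sub = sequence[lo:hi]
    try:
        _, bits, (s, e) = viterbi_align(model, sub)
    except ValueError:
        return
    if bits < _FLOOR_BITS or e <= s:
        return
    out.append((lo + s, lo + e, bits))
    _candidate_envelopes(model, sequence, lo, lo + s, out)
    _candidate_envelopes(model, sequence, lo + e, hi, out)


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


def scan_sequence(
    models: list[ProfileHmm],
    sequence: str,
    sequence_id: str = "sequence",
    report_threshold_bits: float = 10.0,
) -> list[DomainHit]:
    """Scan one protein with one or more models.

    Returns one :class:`DomainHit` per non-overlapping envelope whose best
    forward bit score reaches ``report_threshold_bits``; envelopes from
    different models overlapping by more than half of the shorter envelope
    are resolved in favour of the higher-scoring model.  Hits are sorted
    by position.
    """
    if not models:
        raise ValueError("at least one model is required")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique")

    candidates: list[tuple[ProfileHmm, int, int, float]] = []
    for model in models:
        envs: list[tuple[int, int, float]] = []
        _candidate_envelopes(model, sequence, 0, len(sequence), envs)
        for s, e, _ in envs:
            bits = forward_bits(model, sequence[s:e])
            candidates.append((model, s, e, bits))

    # keep the higher-scoring hit among envelopes overlapping > 50%
    candidates.sort(key=lambda c: (-c[3], c[1], c[0].name))
    kept: list[tuple[ProfileHmm, int, int, float]] = []
    for cand in candidates:
        if all(
            _overlap_frac((cand[1], cand[2]), (k[1], k[2])) <= 0.5 for k in kept
        ):
            kept.append(cand)

    hits = []
    for model, s, e, bits in kept:
        if bits < report_threshold_bits:
            continue
        per_model = {m.name: forward_bits(m, sequence[s:e]) for m in models}
        hits.append(
            DomainHit(
                sequence_id=sequence_id,
                start=s,
                end=e,
                model_name=model.name,
                bit_score=per_model[model.name],
                per_model_scores=per_model,
            )
        )
    hits.sort(key=lambda h: (h.start, h.end, h.model_name))
    return hits


def classify_hit(
    hit: DomainHit,
    canonical_model: str | ProfileHmm,
    vibrio_model: str | ProfileHmm,
    decoy_models: list[str | ProfileHmm] | None = None,
    margin_bits: float = 0.0,
    report_threshold_bits: float = 10.0,
) -> TypeCall:
    """Label a hit canonical / vibrio / reject by score comparison.

    The hit is labelled with the higher-scoring CBM40 type when that score
    beats every decoy score by at least ``margin_bits`` and reaches the
    reporting threshold; otherwise it is rejected.  An exact
    canonical-vs-vibrio tie is labelled canonical with ``tie=True``.
    """
    if margin_bits < 0:
        raise ValueError("margin_bits must be non-negative")

    def _name(m: str | ProfileHmm) -> str:
        return m if isinstance(m, str) else m.name

    can, vib = _name(canonical_model), _name(vibrio_model)
    decoys = [_name(m) for m in (decoy_models or [])]
    for required in [can, vib, *decoys]:
        if required not in hit.per_model_scores:
            raise KeyError(f"hit has no score for model {required!r}")

    s_can = hit.per_model_scores[can]
    s_vib = hit.per_model_scores[vib]
    best_cbm, label = max((s_can, "canonical"), (s_vib, "vibrio"))
    tie = s_can == s_vib
    if tie:
        best_cbm, label = s_can, "canonical"
    other_cbm = s_vib if label == "canonical" else s_can
    best_decoy = max((hit.per_model_scores[d] for d in decoys), default=float("-inf"))
    # recorded margin: best CBM40 score minus best competing score
    margin = best_cbm - max(other_cbm, best_decoy)
    if best_cbm < report_threshold_bits or best_cbm - best_decoy < margin_bits:
        return TypeCall(hit=hit, label="reject", margin_bits=margin, tie=tie)
    return TypeCall(hit=hit, label=label, margin_bits=margin, tie=tie)
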