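"""The 20-letter amino-acid alphabet and background frequencies.

The canonical residue order used throughout the package is the PAML order
``ARNDCQEGHILKMFPSTWYV``.  Ambiguity codes (B, Z, X, U, O, J) are accepted
by the scoring machinery and contribute zero log-odds (scored as
background); they are never counted when estimating emissions.
"""

from __future__ import annotations

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_CHARS = "-."
AMBIGUOUS = "BZXUOJ"

# Robinson & Robinson amino-acid frequencies (the common default null for
# protein HMM scoring), in AA order.
BACKGROUND = np.array(
    [
        0.07805, 0.05129, 0.04487, 0.05364, 0.01925, 0.04264, 0.06295,
        0.07377, 0.02199, 0.05142, 0.09019, 0.05744, 0.02243, 0.03856,
        0.05203, 0.07120, 0.05841, 0.01330, 0.03216, 0.06441,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def encode(sequence: str, *, name: str = "sequence") -> np.ndarray:
    """Map a residue string to integer indices.

    Ambiguity codes map to -1 (scored as background).  Unknown characters
    raise a ``ValueError`` naming the offending character and position.
    """
    seq = sequence.upper()
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        elif ch in AMBIGUOUS:
            out[i] = -1
        else:
            raise ValueError(
                f"unknown residue {ch!r} at position {i} in {name}"
            )
    return out


def is_gap(ch: str) -> bool:
    return ch in GAP_CHARS
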