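"""COSMIC 96-channel trinucleotide conventions.

Single-base substitutions are collapsed onto the pyrimidine strand and
indexed by the six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G),
each in its 16 trinucleotide contexts, giving the canonical 96-channel
ordering used by the COSMIC signature catalogues.
"""

from __future__ import annotations

import numpy as np

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_channels() -> tuple[str, ...]:
    channels = []
    for sub in SUBSTITUTION_TYPES:
        for five in BASES:
            for three in BASES:
                channels.append(f"{five}[{sub}]{three}")
    return tuple(channels)


CHANNELS: tuple[str, ...] = _build_channels()
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """Canonical channel label for a substitution.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine-reference substitutions are reflected onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError(f"not a trinucleotide substitution: {ref}>{alt} in {context}")
    if context[1] != ref:
        raise ValueError(f"context {context} does not match reference base {ref}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label}")
    return label


def parse_channel(label: str) -> tuple[str, str, str]:
    """Split a channel label into (ref, alt, trinucleotide context)."""
    if label not in CHANNEL_INDEX:
        raise ValueError(f"invalid channel label {label!r}")
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


def spectrum_from_channels(labels) -> np.ndarray:
    """96-vector of counts from an iterable of channel labels."""
    out = np.zeros(96, dtype=int)
    for lab in labels:
        out[CHANNEL_INDEX[lab]] += 1
    return out
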