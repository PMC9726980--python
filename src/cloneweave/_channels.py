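"""96-channel trinucleotide substitution encoding.

Channels follow the conventional COSMIC ordering: six pyrimidine-strand
substitution types (C>A, C>G, C>T, T>A, T>C, T>G), each crossed with the 16
flanking-base contexts ordered alphabetically 5' then 3'. Channel index is
``sub_index * 16 + 4 * index(5' base) + index(3' base)``.

Substitutions reported on the purine strand (ref G or A) are
reverse-complemented onto the pyrimidine strand before encoding.
"""

from __future__ import annotations

N_CHANNELS = 96

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_index(ref: str, alt: str, context: str) -> int:
    """Channel for a single-base substitution.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases.
    context : str
        The reference trinucleotide centred on the substituted base
        (5' base, ref base, 3' base). Purine-reference substitutions are
        collapsed onto the pyrimidine strand by reverse complement.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if any(b not in BASES for b in ref + alt + context):
        raise ValueError(f"non-ACGT base in {ref}>{alt} @ {context}")
    if ref in "GA":  # purine strand -> reverse complement
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(context)
    sub = SUB_TYPES.index(f"{ref}>{alt}")
    return sub * 16 + 4 * BASES.index(context[0]) + BASES.index(context[2])


def channel_label(index: int) -> str:
    """COSMIC-style label, e.g. ``A[C>A]G``."""
    if not 0 <= index < N_CHANNELS:
        raise ValueError(f"channel index out of range: {index}")
    sub, ctx = divmod(index, 16)
    five, three = divmod(ctx, 4)
    ref, alt = SUB_TYPES[sub].split(">")
    return f"{BASES[five]}[{ref}>{alt}]{BASES[three]}"


def channel_to_snv(index: int) -> tuple[str, str, str]:
    """Return (ref, alt, trinucleotide context) on the pyrimidine strand."""
    sub, ctx = divmod(index, 16)
    five, three = divmod(ctx, 4)
    ref, alt = SUB_TYPES[sub].split(">")
    return ref, alt, BASES[five] + ref + BASES[three]


CHANNEL_LABELS = tuple(channel_label(i) for i in range(N_CHANNELS))
_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def parse_channel_label(label: str) -> int:
    try:
        return _LABEL_TO_INDEX[label.strip().upper()]
    except KeyError:
        raise ValueError(f"unrecognised channel label: {label!r}") from None
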