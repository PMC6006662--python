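"""Small shared helpers for nucleotide strings."""

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")
MOTIF_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number power of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def validate_nucleotides(seq: str, *, allow_n: bool = True) -> None:
    allowed = VALID_ALPHABET if allow_n else MOTIF_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
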