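import numpy as np
import pytest

from ssrkit.repeat_scan import ScanConfig, SequenceRecord


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def default_config() -> ScanConfig:
    return ScanConfig()


def naive_ssr_oracle(sequence: str, min_repeats: dict[int, int]) -> set[tuple[int, int, str]]:
    """Independent brute-force SSR finder for cross-checking the scanner.

    For every period p and every start of a maximal perfect region
    (checked base-by-base, never via the scanner's vector comparisons),
    extends while sequence[i] == sequence[i - p], trims to whole units and
    applies the primitivity and threshold rules. Returns
    {(start_1based, end_1based, motif)}.
    """
    found = set()
    n = len(sequence)
    for period, threshold in min_repeats.items():
        i = 0
        while i + period <= n:
            motif = sequence[i : i + period]
            if "N" in motif:
                i += 1
                continue
            # region start: position i-1 must NOT continue the pattern
            if (
                i >= 1
                and sequence[i - 1] == sequence[i - 1 + period]
                and sequence[i - 1] != "N"
            ):
                i += 1
                continue
            j = i + period
            while j < n and sequence[j] == sequence[j - period] and sequence[j] != "N":
                j += 1
            region_len = j - i
            n_units = region_len // period
            if n_units >= threshold and _primitive(motif):
                found.add((i + 1, i + n_units * period, motif))
            i += 1
    return found


def _primitive(motif: str) -> bool:
    return all(
        motif != motif[:d] * (len(motif) // d)
        for d in range(1, len(motif))
        if len(motif) % d == 0
    )
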