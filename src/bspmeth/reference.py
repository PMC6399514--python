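"""CpG island detection and in-silico bisulfite conversion of promoter references.

A CpG island (CGI) is a CG-dense stretch classically defined by three
criteria evaluated together: length >= 200 bp, G+C fraction >= 0.50, and an
observed/expected CpG ratio >= 0.60 (Gardiner-Garden & Frommer).  Detection
here follows the sliding-window dialect used by the MethPrimer family of
tools: fixed-size windows are slid across the sequence, qualifying windows
are merged, and the merged interval is re-validated against all three
criteria.  Other dialects (e.g. Takai & Jones) shift and shrink windows
differently and can return different bounds on the same sequence.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine stays C.  ``bisulfite_convert`` produces the two
idealised in-silico references used throughout: the fully-methylated one
(every CpG cytosine protected) and the fully-converted one (every C -> T).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceRegion",
    "IslandParams",
    "CpGIsland",
    "CpGSite",
    "obs_exp_cpg",
    "gc_fraction",
    "detect_cpg_islands",
    "enumerate_cpg_sites",
    "bisulfite_convert",
    "reverse_complement",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRegion:
    """A promoter (or other) reference sequence.

    ``origin_offset`` records the position of base 0 in an external
    coordinate system (e.g. a chromosome); it is carried through to reports
    only and never used in computation.
    """

    id: str
    sequence: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"reference {self.id!r}: invalid bases {sorted(bad)} "
                "(alphabet is A,C,G,T,N)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IslandParams:
    """Criteria and scan granularity for CpG island detection.

    Defaults are the Gardiner-Garden & Frommer values used by the
    MethPrimer family: 200 bp minimum length, GC >= 0.50, observed/expected
    CpG >= 0.60, scanned with 100 bp windows shifted 1 bp at a time.
    Windows with more than ``max_n_frac`` ambiguous (N) bases are skipped.
    """

    min_length: int = 200
    min_gc: float = 0.50
    min_obs_exp: float = 0.60
    window: int = 100
    step: int = 1
    max_n_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.window > self.min_length:
            raise ValueError("window must not exceed min_length")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0.0 <= self.min_gc <= 1.0:
            raise ValueError("min_gc must be in [0, 1]")
        if self.min_obs_exp < 0:
            raise ValueError("min_obs_exp must be >= 0")


@dataclass(frozen=True)
class CpGIsland:
    """A detected island, 0-based half-open on the reference."""

    start: int
    end: int
    gc: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGSite:
    """One CG dinucleotide; ``c_position`` is the 0-based position of the C.

    ``index`` is the 1-based ordinal within the analysed region (CpG1,
    CpG2, ...), assigned in coordinate order.
    """

    index: int
    c_position: int


def gc_fraction(sequence: str) -> float:
    """G+C fraction of a sequence; N bases are excluded from both counts."""
    n_n = sequence.count("N")
    denom = len(sequence) - n_n
    if denom == 0:
        return 0.0
    return (sequence.count("C") + sequence.count("G")) / denom


def obs_exp_cpg(sequence: str) -> float:
    """Observed/expected CpG ratio: (#CG * L) / (#C * #G).

    Returns 0 when the sequence contains no C or no G.  N bases do not
    contribute to any count.
    """
    length = len(sequence)
    if length < 2:
        raise ValueError("obs/exp CpG requires a window of at least 2 bases")
    n_c = sequence.count("C")
    n_g = sequence.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = sequence.count("CG")
    return (n_cg * length) / (n_c * n_g)


def _window_stats(seq: str, window: int, step: int):
    """Vectorised per-window C, G, CG and N counts at each scan start."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cg = np.zeros_like(is_c)
    if len(seq) > 1:
        is_cg[:-1] = is_c[:-1] & (arr[1:] == ord("G"))
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    c_c, c_g, c_n, c_cg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    starts = np.arange(0, len(seq) - window + 1, step)
    ends = starts + window
    return (
        starts,
        c_c[ends] - c_c[starts],
        c_g[ends] - c_g[starts],
        c_n[ends] - c_n[starts],
        # CG dinucleotides wholly inside the window: exclude a CG whose G
        # falls just past the window end.
        c_cg[ends - 1] - c_cg[starts],
    )


def _satisfies(seq: str, start: int, end: int, params: IslandParams) -> bool:
    sub = seq[start:end]
    return (
        end - start >= params.min_length
        and gc_fraction(sub) >= params.min_gc
        and obs_exp_cpg(sub) >= params.min_obs_exp
    )


def _trim(seq: str, start: int, end: int, params: IslandParams):
    """Shrink a merged interval until it re-satisfies GC and obs/exp.

    Bases are removed preferentially from whichever end carries a non-G/C
    terminal base (ties trim the left end), never below ``min_length``.
    Returns None when no qualifying interval remains.
    """
    while end - start >= params.min_length:
        if _satisfies(seq, start, end, params):
            return start, end
        if end - start == params.min_length:
            return None
        if seq[start] not in "CG":
            start += 1
        elif seq[end - 1] not in "CG":
            end -= 1
        else:
            start += 1
    return None


def detect_cpg_islands(
    ref: ReferenceRegion, params: IslandParams | None = None
) -> list[CpGIsland]:
    """Detect CpG islands by merged sliding windows.

    Every window of ``params.window`` bases meeting the GC and obs/exp
    criteria marks its span; overlapping or adjacent qualifying spans are
    unioned, and each union is re-validated (and trimmed if necessary)
    against all three criteria including ``min_length``.  Returns islands
    sorted by position; they are non-overlapping by construction.
    """
    params = params or IslandParams()
    seq = ref.sequence
    if len(seq) < params.window:
        warnings.warn(
            f"reference {ref.id!r} shorter than scan window "
            f"({len(seq)} < {params.window}); no islands reported",
            stacklevel=2,
        )
        return []
    starts, n_c, n_g, n_n, n_cg = _window_stats(seq, params.window, params.step)
    w = params.window
    denom = w - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(denom > 0, (n_c + n_g) / np.maximum(denom, 1), 0.0)
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * w / np.maximum(n_c * n_g, 1), 0.0)
    ok = (gc >= params.min_gc) & (oe >= params.min_obs_exp) & (n_n <= params.max_n_frac * w)

    # Union of qualifying window spans -> maximal runs.
    coverage = np.zeros(len(seq) + 1, dtype=np.int64)
    for s in starts[ok]:
        coverage[s] += 1
        coverage[s + w] -= 1
    covered = np.cumsum(coverage[:-1]) > 0

    islands: list[CpGIsland] = []
    pos = 0
    n = len(seq)
    while pos < n:
        if not covered[pos]:
            pos += 1
            continue
        run_start = pos
        while pos < n and covered[pos]:
            pos += 1
        trimmed = _trim(seq, run_start, pos, params)
        if trimmed is None:
            continue
        a, b = trimmed
        sub = seq[a:b]
        islands.append(CpGIsland(a, b, gc_fraction(sub), obs_exp_cpg(sub)))
    return islands


def enumerate_cpg_sites(
    ref: ReferenceRegion, interval: tuple[int, int] | None = None
) -> list[CpGSite]:
    """Enumerate CG dinucleotides whose C lies in ``interval`` (default: all).

    Ordinals are 1-based in coordinate order, matching the CpG1..CpGn
    numbering convention of clone-based methylation maps.
    """
    start, end = interval if interval is not None else (0, len(ref.sequence))
    if not (0 <= start <= end <= len(ref.sequence)):
        raise ValueError(f"interval [{start}, {end}) outside reference")
    sites = []
    ordinal = 0
    for m in re.finditer("(?=CG)", ref.sequence):
        c_pos = m.start()
        if start <= c_pos < end:
            ordinal += 1
            sites.append(CpGSite(index=ordinal, c_position=c_pos))
    return sites


def bisulfite_convert(sequence: str, mode: str = "cpg_protected") -> str:
    """In-silico bisulfite conversion.

    mode='full': every C becomes T (a fully unmethylated molecule).
    mode='cpg_protected': every C becomes T except a C immediately followed
    by G (a fully CpG-methylated molecule).  Length is always preserved.
    """
    if mode == "full":
        return sequence.replace("C", "T")
    if mode == "cpg_protected":
        return re.sub("C(?!G)", "T", sequence)
    raise ValueError(f"unknown conversion mode {mode!r}")
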