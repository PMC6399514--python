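"""Consensus / PWM motif scanning and CpG-site overlap on promoter sequences.

Motifs are user-editable: an IUPAC consensus with a mismatch budget, a
position weight matrix scored as log-odds against a uniform background
with a threshold expressed as a fraction of the maximum attainable score,
or both (consensus takes precedence when both are given).  The bundled
defaults approximate the factor classes commonly reported on GC-rich
promoters — the Sp1 GC-box, the Oct-1 octamer and the C/EBP palindrome —
and make no claim to reproduce any specific prediction server's hit list.

A CpG site is covered by a hit when both bases of the CG dinucleotide lie
inside the hit interval; methylation of a covered cytosine can interfere
with factor binding, which is what makes covered, phenotype-correlated
sites candidate regulatory positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .reference import CpGSite, ReferenceRegion, reverse_complement

__all__ = ["Motif", "TFBSHit", "scan_motifs", "overlap_cpg", "load_motifs",
           "default_motifs", "DEFAULT_MOTIF_YAML"]

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Motif:
    """One binding motif: consensus with mismatch budget and/or PWM.

    ``pwm`` rows are positions, columns A,C,G,T; each row must sum to 1
    before the log-odds transform.  ``threshold_frac`` is the fraction of
    the maximum log-odds score required for a PWM hit.
    """

    name: str
    consensus: str | None = None
    max_mismatches: int = 0
    pwm: tuple[tuple[float, ...], ...] | None = None
    threshold_frac: float = 0.85

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError(f"motif {self.name!r}: needs a consensus or a PWM")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"motif {self.name!r}: unknown IUPAC code(s) {sorted(bad)}"
                )
            object.__setattr__(self, "consensus", self.consensus.upper())
        if self.pwm is not None:
            arr = np.asarray(self.pwm, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError(f"motif {self.name!r}: PWM must be L x 4")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"motif {self.name!r}: PWM rows must sum to 1")

    @property
    def length(self) -> int:
        if self.consensus is not None:
            return len(self.consensus)
        return len(self.pwm)


@dataclass(frozen=True)
class TFBSHit:
    """A motif occurrence, 0-based half-open on the reference."""

    motif: str
    start: int
    end: int
    strand: str  # '+' | '-'
    score: float
    covered_sites: tuple[int, ...] = ()


def _consensus_hits(seq: str, motif: Motif, strand: str) -> list[TFBSHit]:
    pattern = [IUPAC[c] for c in motif.consensus]
    m = len(pattern)
    hits = []
    for start in range(len(seq) - m + 1):
        mismatches = sum(
            seq[start + i] not in allowed for i, allowed in enumerate(pattern)
        )
        if mismatches <= motif.max_mismatches:
            hits.append(
                TFBSHit(motif.name, start, start + m, strand,
                        score=float(m - mismatches))
            )
    return hits


def _pwm_hits(seq: str, motif: Motif, strand: str) -> list[TFBSHit]:
    pwm = np.asarray(motif.pwm, dtype=float)
    # log-odds vs uniform background, floored to keep zeros finite
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    threshold = motif.threshold_frac * logodds.max(axis=1).sum()
    m = len(pwm)
    hits = []
    for start in range(len(seq) - m + 1):
        window = seq[start : start + m]
        if "N" in window:
            continue
        score = sum(logodds[i, _BASE_INDEX[b]] for i, b in enumerate(window))
        if score >= threshold:
            hits.append(TFBSHit(motif.name, start, start + m, strand, float(score)))
    return hits


def scan_motifs(
    ref: ReferenceRegion,
    motifs: list[Motif],
    both_strands: bool = False,
) -> list[TFBSHit]:
    """Report every window meeting each motif's criterion, sorted by position.

    Overlapping hits are all reported.  Reverse-strand hits (opt-in) are
    found on the reverse complement and mapped back to forward coordinates.
    """
    seq = ref.sequence
    hits: list[TFBSHit] = []
    for motif in motifs:
        scanner = _consensus_hits if motif.consensus is not None else _pwm_hits
        hits.extend(scanner(seq, motif, "+"))
        if both_strands:
            n = len(seq)
            for h in scanner(reverse_complement(seq), motif, "-"):
                hits.append(
                    TFBSHit(h.motif, n - h.end, n - h.start, "-", h.score)
                )
    hits.sort(key=lambda h: (h.start, h.end, h.motif, h.strand))
    return hits


def overlap_cpg(hits: list[TFBSHit], sites: list[CpGSite]):
    """Attach covered CpG ordinals to hits and invert to per-site coverage.

    A site is covered by a hit iff both c_position and c_position+1 lie in
    [start, end).  Returns (hits with covered_sites filled, dict mapping
    site ordinal -> sorted list of covering motif names).
    """
    per_site: dict[int, list[str]] = {s.index: [] for s in sites}
    annotated = []
    for h in hits:
        covered = tuple(
            s.index for s in sites
            if h.start <= s.c_position and s.c_position + 1 < h.end
        )
        for idx in covered:
            per_site[idx].append(h.motif)
        annotated.append(
            TFBSHit(h.motif, h.start, h.end, h.strand, h.score, covered)
        )
    per_site = {k: sorted(set(v)) for k, v in per_site.items()}
    return annotated, per_site


#: Editable default motif set (approximate class consensi, not any
#: prediction server's matrices).
DEFAULT_MOTIF_YAML = """\
motifs:
  - name: Sp1
    consensus: GGGGCGGGGC
    max_mismatches: 1
  - name: Oct-1A
    consensus: ATGCAAAT
    max_mismatches: 1
  - name: C/EBPalp
    consensus: TTGCGCAA
    max_mismatches: 1
"""


def default_motifs() -> list[Motif]:
    return _parse_motif_config(yaml.safe_load(DEFAULT_MOTIF_YAML))


def _parse_motif_config(cfg: dict) -> list[Motif]:
    motifs = []
    for entry in cfg["motifs"]:
        motifs.append(
            Motif(
                name=entry["name"],
                consensus=entry.get("consensus"),
                max_mismatches=int(entry.get("max_mismatches", 0)),
                pwm=tuple(map(tuple, entry["pwm"])) if "pwm" in entry else None,
                threshold_frac=float(entry.get("threshold_frac", 0.85)),
            )
        )
    return motifs


def load_motifs(path) -> list[Motif]:
    """Load motif definitions from a YAML file (see DEFAULT_MOTIF_YAML)."""
    with open(path) as fh:
        return _parse_motif_config(yaml.safe_load(fh))
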