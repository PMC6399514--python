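"""Alignment, QC and methylation calling for cloned BSP amplicon reads.

Each Sanger-sequenced clone is one molecule.  Reads are globally aligned to
the in-silico converted reference (CpG cytosines protected) with
bisulfite-aware scoring: a read T opposite a reference C scores as a match,
reflecting C->T chemistry on the sequenced strand; the reverse pairing
(read C opposite reference T) stays a mismatch.  At a CpG cytosine column
the retained read base then carries the methylation signal: C = methylated,
T = unmethylated, anything else (gap, A, G, N) = missing.

Quality control follows QUMA-style conventions: a clone passes when its
bisulfite conversion efficiency (fraction of non-CpG reference cytosines
read as T) and its sequence identity both clear their thresholds.  Failing
clones are excluded from every rate and logged with a reason, never
silently dropped.

The group-level statistic is the integral methylation rate: methylated CpG
calls as a fraction of all non-missing calls across every sequenced clone
in the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .reference import CpGSite, reverse_complement

__all__ = [
    "CloneRead",
    "AlignedClone",
    "CloneQC",
    "CloneCallMatrix",
    "GroupMethylationSummary",
    "METHYLATED",
    "UNMETHYLATED",
    "MISSING",
    "align_clone",
    "clone_qc",
    "call_clone",
    "build_call_matrix",
    "per_site_rates",
    "integral_rate",
    "summarize_group",
    "lollipop_text",
    "parse_lollipop_text",
    "lollipop_svg",
    "process_clones",
]

METHYLATED = "M"
UNMETHYLATED = "U"
MISSING = "."

# filled / open / absent glyphs of the text lollipop rendering
_GLYPH = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "·"}
_GLYPH_INV = {v: k for k, v in _GLYPH.items()}

#: Affine gap model: opening a gap costs 4 and each gapped base costs 1,
#: so a length-k gap scores -(4 + k).
GAP_OPEN = 4
GAP_EXTEND = 1
MATCH = 1
MISMATCH = -1


@dataclass(frozen=True)
class CloneRead:
    clone_id: str
    group_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id!r}: empty sequence")


@dataclass
class AlignedClone:
    """A clone after global alignment to the converted reference.

    ``ref_to_read`` maps each reference position covered by the alignment
    to the read base placed opposite it (None where the read has a gap).
    ``identity`` is computed over aligned columns, excluding columns where
    the reference base is C and the read base is C or T — those columns
    carry the methylation signal, not sequence identity.
    """

    clone_id: str
    group_id: str
    orientation: str  # "forward" | "reverse_complement"
    score: float
    identity: float
    ref_to_read: dict[int, str | None]
    alignable: bool = True


def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = MATCH if a == b else MISMATCH
    matrix["C", "T"] = MATCH  # bisulfite asymmetry: ref C / read T
    for x in "ACGTN":
        matrix[x, "N"] = 0.0
        matrix["N", x] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    # Amplicons are primer-anchored but may cover only part of the supplied
    # reference, so end gaps are free (semi-global); internal gaps stay affine.
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _ref_to_read_map(alignment) -> dict[int, str | None]:
    read = alignment.query
    mapping: dict[int, str | None] = {}
    blocks_ref, blocks_read = alignment.aligned
    prev_ref_end = None
    for (rs, re_), (qs, _qe) in zip(blocks_ref, blocks_read):
        if prev_ref_end is not None:
            for p in range(prev_ref_end, rs):  # read gap across these ref bases
                mapping[p] = None
        for off in range(re_ - rs):
            mapping[rs + off] = read[qs + off]
        prev_ref_end = re_
    return mapping


def _identity(converted_ref: str, mapping: dict[int, str | None]) -> float:
    matches = 0
    total = 0
    for pos, base in mapping.items():
        if base is None:
            continue
        r = converted_ref[pos]
        if r == "C" and base in "CT":
            continue  # methylation-informative column, not identity-informative
        total += 1
        if base == r:
            matches += 1
    return matches / total if total else 0.0


def align_clone(
    read: CloneRead,
    converted_ref: str,
    sites: list[CpGSite] | None = None,
    min_score_frac: float = 0.5,
) -> AlignedClone:
    """Align a clone read to the cpg-protected converted reference.

    Alignment is end-to-end over the overlap (free end gaps, affine
    internal gaps).  Both orientations are tried and the better score
    kept; an exact tie prefers forward with a warning.  A best score below
    ``min_score_frac * min(len(read), len(ref))`` flags the clone
    unalignable (no plausible overlap).
    """
    fwd = _ALIGNER.align(converted_ref, read.sequence)
    fwd_score = fwd.score
    rc_seq = reverse_complement(read.sequence)
    rc_score = _ALIGNER.score(converted_ref, rc_seq)
    if fwd_score == rc_score:
        warnings.warn(
            f"clone {read.clone_id!r}: orientation tie, preferring forward",
            stacklevel=2,
        )
    if rc_score > fwd_score:
        orientation, score = "reverse_complement", rc_score
        alignment = _ALIGNER.align(converted_ref, rc_seq)[0]
    else:
        orientation, score = "forward", fwd_score
        alignment = fwd[0]
    if score < min_score_frac * min(len(read.sequence), len(converted_ref)):
        return AlignedClone(
            read.clone_id, read.group_id, orientation, score, 0.0, {}, alignable=False
        )
    mapping = _ref_to_read_map(alignment)
    return AlignedClone(
        clone_id=read.clone_id,
        group_id=read.group_id,
        orientation=orientation,
        score=score,
        identity=_identity(converted_ref, mapping),
        ref_to_read=mapping,
    )


@dataclass
class CloneQC:
    clone_id: str
    conversion_rate: float | None
    identity: float
    n_ambiguous_cpg: int
    passed: bool
    reason: str = ""


def clone_qc(
    aligned: AlignedClone,
    original_ref: str,
    sites: list[CpGSite],
    min_conversion: float = 0.95,
    min_identity: float = 0.90,
) -> CloneQC:
    """QC a clone: conversion efficiency over non-CpG reference cytosines.

    A non-CpG reference C read as T was converted; read as C it escaped
    conversion.  Other bases or gaps at those positions are uninformative.
    """
    if not aligned.alignable:
        return CloneQC(aligned.clone_id, None, 0.0, 0, False, "unalignable")
    cpg_c = {s.c_position for s in sites}
    n_conv = n_unconv = 0
    for pos, base in aligned.ref_to_read.items():
        if original_ref[pos] != "C" or pos in cpg_c:
            continue
        if base == "T":
            n_conv += 1
        elif base == "C":
            n_unconv += 1
    n_ambig = sum(
        1 for s in sites if aligned.ref_to_read.get(s.c_position) not in ("C", "T")
    )
    if n_conv + n_unconv == 0:
        return CloneQC(
            aligned.clone_id, None, aligned.identity, n_ambig, False,
            "no informative non-CpG cytosines; conversion rate undefined",
        )
    conv = n_conv / (n_conv + n_unconv)
    reasons = []
    if conv < min_conversion:
        reasons.append(f"conversion {conv:.3f} < {min_conversion}")
    if aligned.identity < min_identity:
        reasons.append(f"identity {aligned.identity:.3f} < {min_identity}")
    return CloneQC(
        aligned.clone_id, conv, aligned.identity, n_ambig,
        not reasons, "; ".join(reasons),
    )


def call_clone(aligned: AlignedClone, sites: list[CpGSite]) -> list[str]:
    """Per-site methylation calls: C -> methylated, T -> unmethylated, else missing."""
    calls = []
    for site in sites:
        base = aligned.ref_to_read.get(site.c_position)
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(MISSING)
    return calls


@dataclass
class CloneCallMatrix:
    """Clones x CpG sites call matrix for one group (e.g. one week).

    ``calls`` is a DataFrame indexed by clone id with 1-based site ordinals
    as columns and cells in {M, U, .}.  Only QC-passing clones belong here.
    """

    group_id: str
    calls: pd.DataFrame

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    @property
    def site_ordinals(self) -> list[int]:
        return list(self.calls.columns)


def build_call_matrix(
    group_id: str, calls_by_clone: dict[str, list[str]], n_sites: int
) -> CloneCallMatrix:
    df = pd.DataFrame.from_dict(
        calls_by_clone, orient="index", columns=range(1, n_sites + 1)
    )
    df.index.name = "clone_id"
    return CloneCallMatrix(group_id, df)


def per_site_rates(matrix: CloneCallMatrix) -> pd.Series:
    """Methylation rate per site: methylated / (methylated + unmethylated).

    A site with no valid (non-missing) call gets NaN, never 0.
    """
    meth = (matrix.calls == METHYLATED).sum(axis=0)
    valid = meth + (matrix.calls == UNMETHYLATED).sum(axis=0)
    rates = meth / valid.where(valid > 0)
    rates.name = "rate"
    return rates


def integral_rate(matrix: CloneCallMatrix) -> float:
    """Overall rate: total methylated calls / total non-missing calls."""
    meth = int((matrix.calls == METHYLATED).sum().sum())
    unmeth = int((matrix.calls == UNMETHYLATED).sum().sum())
    if meth + unmeth == 0:
        raise ValueError(
            f"group {matrix.group_id!r}: no valid calls; integral rate undefined"
        )
    return meth / (meth + unmeth)


@dataclass
class GroupMethylationSummary:
    group_id: str
    per_site_rate: pd.Series
    integral_rate: float
    valid_calls: pd.Series
    n_clones: int


def summarize_group(matrix: CloneCallMatrix) -> GroupMethylationSummary:
    meth = (matrix.calls == METHYLATED).sum(axis=0)
    valid = meth + (matrix.calls == UNMETHYLATED).sum(axis=0)
    return GroupMethylationSummary(
        group_id=matrix.group_id,
        per_site_rate=per_site_rates(matrix),
        integral_rate=integral_rate(matrix),
        valid_calls=valid,
        n_clones=matrix.n_clones,
    )


def lollipop_text(matrix: CloneCallMatrix) -> str:
    """Text lollipop rendering: one row per clone, filled=methylated."""
    lines = [f"# group={matrix.group_id} sites=" + ",".join(map(str, matrix.site_ordinals))]
    for clone_id, row in matrix.calls.iterrows():
        lines.append(f"{clone_id}\t" + "".join(_GLYPH[c] for c in row))
    return "\n".join(lines) + "\n"


def parse_lollipop_text(text: str) -> CloneCallMatrix:
    """Inverse of :func:`lollipop_text`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    group_id = header.split("group=")[1].split()[0]
    ordinals = [int(x) for x in header.split("sites=")[1].split(",")]
    calls = {}
    for line in lines[1:]:
        clone_id, glyphs = line.split("\t")
        calls[clone_id] = [_GLYPH_INV[g] for g in glyphs]
    df = pd.DataFrame.from_dict(calls, orient="index", columns=ordinals)
    df.index.name = "clone_id"
    return CloneCallMatrix(group_id, df)


def lollipop_svg(matrix: CloneCallMatrix, path) -> None:
    """Render the clones-by-sites lollipop diagram to an SVG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_clones, n_sites = matrix.calls.shape
    fig, ax = plt.subplots(figsize=(0.3 * n_sites + 1.5, 0.25 * n_clones + 1))
    vals = matrix.calls.to_numpy()
    rows, cols = np.indices(vals.shape)
    x = cols + 1
    y = n_clones - rows
    for call, face in ((METHYLATED, "black"), (UNMETHYLATED, "white")):
        mask = vals == call
        ax.scatter(x[mask], y[mask], s=40, facecolors=face,
                   edgecolors="black", zorder=3)
    for i in range(n_clones):
        ax.plot([1, n_sites], [n_clones - i] * 2, color="0.6", lw=0.8, zorder=1)
    ax.set_xticks(range(1, n_sites + 1))
    ax.set_yticks([])
    ax.set_xlabel("CpG site")
    ax.set_title(f"{matrix.group_id} (n={n_clones} clones)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def process_clones(
    reads: list[CloneRead],
    original_ref: str,
    converted_ref: str,
    sites: list[CpGSite],
    min_conversion: float = 0.95,
    min_identity: float = 0.90,
    min_score_frac: float = 0.5,
    crop_flank: int = 150,
) -> tuple[dict[str, CloneCallMatrix], pd.DataFrame]:
    """Align, QC and call every read; one call matrix per group.

    Alignment is restricted to the window spanning the CpG sites plus
    ``crop_flank`` bases each side — BSP amplicons target that window, and
    cropping keeps the dynamic program small on long references.  Returns
    (matrices by group, per-clone QC table).  The QC table records every
    read, passing or not, with its failure reason.
    """
    lo = max(0, min(s.c_position for s in sites) - crop_flank)
    hi = min(len(original_ref), max(s.c_position for s in sites) + 2 + crop_flank)
    cropped_orig = original_ref[lo:hi]
    cropped_conv = converted_ref[lo:hi]
    shifted_sites = [CpGSite(s.index, s.c_position - lo) for s in sites]
    qc_rows = []
    by_group: dict[str, dict[str, list[str]]] = {}
    for read in reads:
        aligned = align_clone(read, cropped_conv, shifted_sites, min_score_frac)
        qc = clone_qc(aligned, cropped_orig, shifted_sites, min_conversion, min_identity)
        qc_rows.append(
            {
                "clone_id": read.clone_id,
                "group_id": read.group_id,
                "orientation": aligned.orientation,
                "conversion_rate": qc.conversion_rate,
                "identity": qc.identity,
                "n_ambiguous_cpg": qc.n_ambiguous_cpg,
                "passed": qc.passed,
                "reason": qc.reason,
            }
        )
        if qc.passed:
            by_group.setdefault(read.group_id, {})[read.clone_id] = call_clone(
                aligned, shifted_sites
            )
    matrices = {
        g: build_call_matrix(g, calls, len(sites)) for g, calls in by_group.items()
    }
    return matrices, pd.DataFrame(qc_rows)
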