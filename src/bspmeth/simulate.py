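"""Synthetic BSP studies with known ground truth.

The generator emulates the sampling design of a clone-based promoter
methylation study over a laying cycle: a ~1 kb promoter whose CpG-island
core carries 14 CpG sites, 12-16 sequenced clones per shell-gland tissue
with three tissues per week over eight weeks (25-60), per-site methylation
probabilities whose weekly means ramp from ~0.84 to ~0.91, incomplete
bisulfite conversion, sequencing errors, weekly colorimeter measurements
matching the published weekly means/SDs, and qPCR Ct tables with
expression fold-changes that fall across the cycle.

Every artifact is deterministic given (config, seed): each output draws
from its own seeded substream (reference = 0, clones = 1, color = 2,
Ct = 3) so files can be regenerated independently.  The ground truth —
planted site positions, the per-week/per-site probability matrix, every
clone's methylation states, color means and fold-changes — is serialized
alongside the data and is sufficient to score every estimator in the
pipeline.

What the generator does not emulate: chromatogram-level noise, clone
lineage effects within a tissue (a beta-binomial per-clone mode is
available but off by default, since pure Bernoulli matches a design with
no stated within-week dispersion), and PCR/cloning bias.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .calling import CloneRead
from .reference import (
    ReferenceRegion,
    bisulfite_convert,
    detect_cpg_islands,
    enumerate_cpg_sites,
    reverse_complement,
)

__all__ = [
    "SyntheticConfig",
    "ReferenceTruth",
    "generate_reference",
    "generate_methylation_states",
    "generate_clones",
    "generate_color",
    "generate_ct",
    "generate_bundle",
]

_DEFAULT_WEEKS = tuple(sorted(datasets.OVERALL_METHYLATION_BY_WEEK))
_DEFAULT_FOLDS = {25: 1.00, 30: 0.97, 35: 0.65, 40: 0.62,
                  45: 0.60, 50: 0.33, 55: 0.30, 60: 0.28}


def _default_site_prob(weeks, n_sites) -> dict[int, tuple[float, ...]]:
    """Per-week per-site probabilities: the published pooled site profile
    rescaled so each week's mean tracks the published weekly ramp."""
    profile = np.resize(datasets.SITE_METHYLATION_PROFILE, n_sites)
    profile = profile / profile.mean()
    return {
        w: tuple(np.clip(profile * datasets.OVERALL_METHYLATION_BY_WEEK.get(w, 0.88), 0.0, 1.0))
        for w in weeks
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the published design: eight sampled weeks, 14 CpG
    sites, 15 clones x 3 tissues per week, 1% conversion failure, 0.2%
    substitution sequencing error, weekly color distributions equal to the
    published weekly means/SDs/sample sizes, and fold-changes that decline
    over the cycle with the first sampled week as calibrator.
    """

    weeks: tuple[int, ...] = _DEFAULT_WEEKS
    n_sites: int = 14
    ref_length: int = 1000
    core_length: int = 250
    core_gc: float = 0.60
    amplicon_pad: int = 25
    per_week_site_prob: dict[int, tuple[float, ...]] | None = None
    clones_per_tissue: int = 15
    n_tissues: int = 3
    conversion_failure_rate: float = 0.01
    sequencing_error_rate: float = 0.002
    indel_error_rate: float = 0.0
    revcomp_fraction: float = 0.5
    beta_binomial_kappa: float | None = None  # None = pure Bernoulli
    color_weeks: tuple[int, ...] = tuple(datasets.EGGSHELL_COLOR_WEEKLY.index)
    color_means: dict[int, float] = field(
        default_factory=lambda: datasets.EGGSHELL_COLOR_WEEKLY["mean"].to_dict()
    )
    color_sds: dict[int, float] = field(
        default_factory=lambda: datasets.EGGSHELL_COLOR_WEEKLY["sd"].to_dict()
    )
    eggs_per_week: dict[int, int] = field(
        default_factory=lambda: datasets.EGGSHELL_COLOR_WEEKLY["n"].to_dict()
    )
    position_sd: float = 1.0
    expression_fold_by_week: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_FOLDS)
    )
    samples_per_week: int = 5
    ct_replicates: int = 3
    ct_noise_sd: float = 0.15
    reference_ct_mean: float = 20.0
    baseline_delta_ct: float = 3.0
    #: TF motif instances planted over CpG ordinals; the default mirrors the
    #: published coverage pattern (sites 2,3,5,6,8,9 under C/EBP, Sp1 and
    #: Oct-1 class sites).  Empty tuple = no planting.
    planted_motifs: tuple[tuple[str, int], ...] = (
        ("C/EBPalp", 2), ("C/EBPalp", 3), ("Sp1", 5),
        ("Sp1", 6), ("Oct-1A", 8), ("Oct-1A", 9),
    )

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.per_week_site_prob is None:
            self.per_week_site_prob = _default_site_prob(self.weeks, self.n_sites)
        for w, probs in self.per_week_site_prob.items():
            if len(probs) != self.n_sites:
                raise ValueError(f"week {w}: need {self.n_sites} site probabilities")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"week {w}: probabilities must be in [0, 1]")
        if self.n_sites * 4 > self.core_length:
            raise ValueError("core too short for the requested number of CpG sites")

    @property
    def clones_per_week(self) -> int:
        return self.clones_per_tissue * self.n_tissues


@dataclass
class ReferenceTruth:
    """Planted structure of a synthetic reference."""

    site_positions: tuple[int, ...]
    core_interval: tuple[int, int]
    amplicon_interval: tuple[int, int]
    #: (motif name, covered ordinal, start, end) per planted instance
    motif_placements: tuple[tuple[str, int, int, int], ...] = ()


#: Plantable motif instances: sequence written into the reference and the
#: offset of the CG dinucleotide that lands on the covered CpG site.  The
#: Oct-1 instance deviates from the octamer consensus by one base (within
#: the default mismatch budget) because the consensus itself has no CG.
_PLANT_INSTANCES = {
    "Sp1": ("GGGGCGGGGC", 4),
    "C/EBPalp": ("TTGCGCAA", 3),
    "Oct-1A": ("ATGCGAAT", 3),
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _repair_cg(seq: list[str], planted: set[int], protected: set[int], rng) -> None:
    """Destroy accidental CG dinucleotides, leaving planted ones intact.

    Positions in ``protected`` (planted motif spans) are never mutated; a
    CG straddling a protected G is broken by mutating its C instead.
    """
    for _ in range(10 * len(seq)):
        bad = [
            i for i in range(len(seq) - 1)
            if seq[i] == "C" and seq[i + 1] == "G" and i not in planted
        ]
        if not bad:
            return
        for i in bad:
            if i + 1 not in protected:
                seq[i + 1] = "A" if rng.random() < 0.5 else "T"
            elif i not in protected:
                seq[i] = "A" if rng.random() < 0.5 else "T"
            else:
                raise RuntimeError("accidental CG inside a protected motif")
    raise RuntimeError("could not repair accidental CpG dinucleotides")


def generate_reference(
    config: SyntheticConfig, seed: int
) -> tuple[ReferenceRegion, ReferenceTruth]:
    """A ~1 kb promoter with a CpG-island core holding exactly n_sites CGs.

    The core is GC-rich (``core_gc``) with the planted CGs evenly spaced;
    flanks are AT-rich and CG-free, so the planted sites are the only CG
    dinucleotides in the whole sequence.  Construction is retried (from
    the same stream) until island detection returns a single island
    containing every planted site.
    """
    rng = _rng(seed, 0)
    n = config.ref_length
    core_len = config.core_length
    core_start = (n - core_len) // 2
    spacing = core_len / config.n_sites
    site_offsets = [int((i + 0.5) * spacing) for i in range(config.n_sites)]

    for _attempt in range(50):
        seq = list("".join(rng.choice(list("ACGT"), size=n, p=[0.4, 0.1, 0.1, 0.4])))
        # GC-rich core with exact composition
        n_gc = int(round(config.core_gc * core_len))
        n_c = n_gc // 2
        n_g = n_gc - n_c
        fill_c = n_c - config.n_sites
        fill_g = n_g - config.n_sites
        n_at = core_len - 2 * config.n_sites - fill_c - fill_g
        fill = (["C"] * fill_c + ["G"] * fill_g
                + ["A"] * (n_at // 2) + ["T"] * (n_at - n_at // 2))
        rng.shuffle(fill)
        core = [None] * core_len
        for off in site_offsets:
            core[off], core[off + 1] = "C", "G"
        it = iter(fill)
        core = [next(it) if b is None else b for b in core]
        seq[core_start : core_start + core_len] = core

        planted = {core_start + off for off in site_offsets}
        # overwrite around chosen sites with TF motif instances, CG-on-site
        placements = []
        protected: set[int] = set()
        feasible = True
        for name, ordinal in config.planted_motifs:
            instance, cg_off = _PLANT_INSTANCES[name]
            if not 1 <= ordinal <= config.n_sites:
                raise ValueError(f"planted motif ordinal {ordinal} out of range")
            site_pos = core_start + site_offsets[ordinal - 1]
            start = site_pos - cg_off
            end = start + len(instance)
            if start < 0 or end > n or (protected & set(range(start, end))):
                feasible = False
                break
            seq[start:end] = list(instance)
            protected.update(range(start, end))
            placements.append((name, ordinal, start, end))
        if not feasible:
            raise ValueError("planted motifs overlap; space sites further apart")
        try:
            _repair_cg(seq, planted, protected, rng)
        except RuntimeError:
            continue
        sequence = "".join(seq)
        ref = ReferenceRegion(id=f"synthetic_promoter_seed{seed}", sequence=sequence)
        sites = enumerate_cpg_sites(ref)
        if [s.c_position for s in sites] != sorted(planted):
            continue
        islands = detect_cpg_islands(ref)
        containing = [
            isl for isl in islands
            if all(isl.start <= p and p + 1 < isl.end for p in planted)
        ]
        if not (len(islands) == 1 and containing):
            continue
        if config.planted_motifs and not _motif_coverage_ok(ref, sites, config):
            continue
        amp = (
            max(0, core_start - config.amplicon_pad),
            min(n, core_start + core_len + config.amplicon_pad),
        )
        return ref, ReferenceTruth(
            site_positions=tuple(sorted(planted)),
            core_interval=(core_start, core_start + core_len),
            amplicon_interval=amp,
            motif_placements=tuple(placements),
        )
    raise RuntimeError("failed to construct a qualifying synthetic reference")


def _motif_coverage_ok(ref, sites, config) -> bool:
    """Default-motif scan must cover exactly the planted ordinals (no
    spurious near-matches covering other sites)."""
    from .tfbs import default_motifs, overlap_cpg, scan_motifs

    _, per_site = overlap_cpg(scan_motifs(ref, default_motifs()), sites)
    covered = {s for s, names in per_site.items() if names}
    return covered == {o for _, o in config.planted_motifs}


def generate_methylation_states(
    config: SyntheticConfig, seed: int
) -> dict[int, np.ndarray]:
    """Planted per-clone methylation states: week -> (clones x sites) 0/1.

    Pure Bernoulli per cell by default; with ``beta_binomial_kappa`` set,
    each clone draws its own site probability from Beta(kappa*p,
    kappa*(1-p)) to mimic cell/allele mosaicism.
    """
    rng = _rng(seed, 1)
    states = {}
    for week in config.weeks:
        p = np.asarray(config.per_week_site_prob[week])
        shape = (config.clones_per_week, config.n_sites)
        if config.beta_binomial_kappa is not None:
            k = config.beta_binomial_kappa
            a = np.maximum(k * p, 1e-9)
            b = np.maximum(k * (1 - p), 1e-9)
            p_clone = rng.beta(a, b, size=shape)
            states[week] = (rng.random(shape) < p_clone).astype(np.int8)
        else:
            states[week] = (rng.random(shape) < p).astype(np.int8)
    return states


_BASE_LOOKUP = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LOOKUP[_b] = _i


def generate_clones(
    ref: ReferenceRegion,
    truth: ReferenceTruth,
    config: SyntheticConfig,
    seed: int,
    states: dict[int, np.ndarray] | None = None,
) -> tuple[list[CloneRead], pd.DataFrame, dict[int, np.ndarray]]:
    """Simulate sequenced BSP clones from planted methylation states.

    Each clone read is the bisulfite image of the amplicon: methylated CpG
    cytosines stay C; every other C converts to T except with probability
    ``conversion_failure_rate``; substitution errors hit each base with
    probability ``sequencing_error_rate`` (opt-in indels exercise gapped
    alignment); a ``revcomp_fraction`` of clones is emitted
    reverse-complemented, as cloning inserts either way round.

    Returns (reads, manifest, states).  The manifest maps clone ids to
    week groups and tissues; clone ids are ordered w{week}_t{tissue}_c{k}.
    """
    if states is None:
        states = generate_methylation_states(config, seed)
    rng = _rng(seed, 4)
    a0, a1 = truth.amplicon_interval
    amplicon = np.frombuffer(ref.sequence[a0:a1].encode("ascii"), dtype=np.uint8)
    length = len(amplicon)
    site_offsets = np.asarray([p - a0 for p in truth.site_positions])
    c_positions = np.flatnonzero(amplicon == ord("C"))
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[CloneRead] = []
    manifest_rows = []
    for week in config.weeks:
        week_states = states[week]
        idx = 0
        for tissue in range(1, config.n_tissues + 1):
            for k in range(1, config.clones_per_tissue + 1):
                clone_states = week_states[idx]
                idx += 1
                bases = amplicon.copy()
                # bisulfite image: every C -> T unless methylated CpG or a
                # conversion failure
                converted = rng.random(len(c_positions)) >= config.conversion_failure_rate
                bases[c_positions[converted]] = ord("T")
                bases[site_offsets[clone_states.astype(bool)]] = ord("C")
                # substitution sequencing errors
                err = np.flatnonzero(rng.random(length) < config.sequencing_error_rate)
                if len(err):
                    shift = rng.integers(1, 4, size=len(err))
                    cur_idx = _BASE_LOOKUP[bases[err]]
                    bases[err] = alphabet[(cur_idx + shift) % 4]
                seq = bases.tobytes().decode("ascii")
                if config.indel_error_rate:
                    out = []
                    for b in seq:
                        if rng.random() < config.indel_error_rate:
                            if rng.random() < 0.5:
                                continue  # deletion
                            out.append(b)
                            out.append("ACGT"[rng.integers(4)])  # insertion
                        else:
                            out.append(b)
                    seq = "".join(out)
                if rng.random() < config.revcomp_fraction:
                    seq = reverse_complement(seq)
                clone_id = f"w{week}_t{tissue}_c{k}"
                reads.append(CloneRead(clone_id, str(week), seq))
                manifest_rows.append(
                    {"clone_id": clone_id, "group_id": str(week), "tissue": tissue}
                )
    return reads, pd.DataFrame(manifest_rows), states


def generate_color(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Per-egg colorimeter table: week, egg_id, r1, r2, r3, exclude.

    Each egg draws a latent value ~ Normal(mean_w, sd_w); the three
    position readings add independent Normal(0, position_sd) noise.
    """
    rng = _rng(seed, 2)
    rows = []
    for week in config.color_weeks:
        n = config.eggs_per_week[week]
        latent = rng.normal(config.color_means[week], config.color_sds[week], size=n)
        readings = latent[:, None] + rng.normal(0, config.position_sd, size=(n, 3))
        for i in range(n):
            rows.append(
                {"week": week, "egg_id": f"w{week}_e{i + 1}",
                 "r1": round(readings[i, 0], 3), "r2": round(readings[i, 1], 3),
                 "r3": round(readings[i, 2], 3), "exclude": 0}
            )
    return pd.DataFrame(rows)


def generate_ct(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """qPCR Ct table: sample_id, week, gene_role, replicate, ct.

    Per sample, a reference baseline Ct ~ Normal(reference_ct_mean,
    ct_noise_sd); replicate reference Cts add Normal(0, ct_noise_sd), and
    replicate target Cts are baseline + baseline_delta_ct - log2(fold_w)
    plus the same noise, so at zero noise rq recovers the fold exactly.
    """
    rng = _rng(seed, 3)
    rows = []
    for week in config.weeks:
        fold = config.expression_fold_by_week[week]
        for s in range(1, config.samples_per_week + 1):
            sample = f"w{week}_s{s}"
            base = config.reference_ct_mean + (
                rng.normal(0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
            )
            target_mean = base + config.baseline_delta_ct - np.log2(fold)
            for rep in range(1, config.ct_replicates + 1):
                noise_r = rng.normal(0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                noise_t = rng.normal(0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                rows.append({"sample_id": sample, "week": week, "gene_role": "reference",
                             "replicate": rep, "ct": round(base + noise_r, 4)})
                rows.append({"sample_id": sample, "week": week, "gene_role": "target",
                             "replicate": rep, "ct": round(target_mean + noise_t, 4)})
    return pd.DataFrame(rows)


def generate_bundle(config: SyntheticConfig, seed: int, out_dir) -> dict:
    """Write every pipeline input plus ground truth to ``out_dir``.

    Files: reference.fa, clones.fa, manifest.tsv, color.tsv, ct.tsv,
    truth.json, bundle.json (file list + seed).  The write is atomic: a
    partial failure leaves no bundle behind.
    """
    from .io import write_fasta  # local import to avoid cycles

    out_dir = Path(out_dir)
    ref, truth = generate_reference(config, seed)
    reads, manifest, states = generate_clones(ref, truth, config, seed)
    color = generate_color(config, seed)
    ct = generate_ct(config, seed)

    truth_doc = {
        "seed": int(seed),
        "site_positions": list(truth.site_positions),
        "core_interval": list(truth.core_interval),
        "amplicon_interval": list(truth.amplicon_interval),
        "motif_placements": [list(m) for m in truth.motif_placements],
        "per_week_site_prob": {
            str(w): list(map(float, p)) for w, p in config.per_week_site_prob.items()
        },
        "planted_week_rates": {
            str(w): float(np.mean(config.per_week_site_prob[w])) for w in config.weeks
        },
        "clone_states": {
            str(w): states[w].tolist() for w in config.weeks
        },
        "color_means": {str(w): config.color_means[w] for w in config.color_weeks},
        "expression_fold_by_week": {
            str(w): config.expression_fold_by_week[w] for w in config.weeks
        },
    }

    tmp = Path(tempfile.mkdtemp(prefix=".bundle_", dir=out_dir.parent if out_dir.parent.exists() else None))
    try:
        write_fasta(tmp / "reference.fa", [(ref.id, ref.sequence)])
        write_fasta(tmp / "clones.fa", [(r.clone_id, r.sequence) for r in reads])
        manifest.to_csv(tmp / "manifest.tsv", sep="\t", index=False)
        color.to_csv(tmp / "color.tsv", sep="\t", index=False)
        ct.to_csv(tmp / "ct.tsv", sep="\t", index=False)
        (tmp / "truth.json").write_text(json.dumps(truth_doc, indent=1))
        files = ["reference.fa", "clones.fa", "manifest.tsv", "color.tsv",
                 "ct.tsv", "truth.json"]
        (tmp / "bundle.json").write_text(
            json.dumps({"seed": int(seed), "files": files}, indent=1)
        )
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return truth_doc
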