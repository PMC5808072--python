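"""Synthetic inputs: V-region clone sets under an AID-biased substitution
model, and ChIP/input binned count tracks with planted lamina domains.

The clone simulator emulates Sanger sequencing of independent bacterial
colonies carrying a PCR-amplified V-region: each clone derives independently
from the reference (no clonal phylogeny), with per-site substitution
probability mu at ordinary positions and h*mu at AID hotspot positions (the
C of WRCY / G of RGYW). An AID-null condition attenuates all rates by a
small multiplier, mirroring the near-complete loss of both background and
induced mutation in AID-deficient cells.

The binding simulator draws per-bin read counts from a negative binomial
(Poisson in the infinite-dispersion limit) around a background mean, with
planted domains whose mean is multiplied by a per-condition enrichment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import AnnotationSet, BinnedTrack, GenomeSpec, Interval
from .shm import BASES, ReferenceSequence, hotspot_labels

__all__ = [
    "SHMParams",
    "CloneSet",
    "PlantedDomain",
    "PlantedDomainSpec",
    "FixtureConfig",
    "generate_reference",
    "simulate_clones",
    "simulate_binding_tracks",
    "write_fixture_set",
    "expected_hotspot_fraction",
    "aid_spectrum",
    "default_fixture_config",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def uniform_spectrum() -> np.ndarray:
    """Uniform substitution spectrum: each alternative base equally likely."""
    m = np.ones((4, 4))
    np.fill_diagonal(m, 0.0)
    return m


def aid_spectrum(deamination_weight: float = 4.0) -> np.ndarray:
    """Deamination-like spectrum preset: upweights C->T and G->A."""
    m = uniform_spectrum()
    m[_BASE_INDEX["C"], _BASE_INDEX["T"]] = deamination_weight
    m[_BASE_INDEX["G"], _BASE_INDEX["A"]] = deamination_weight
    return m


@dataclass(frozen=True)
class SHMParams:
    """Parameters of the per-clone substitution model.

    mu_background : substitutions per bp per clone at non-hotspot sites.
    hotspot_multiplier : rate multiplier at hotspot sites (>= 1).
    aid_active : when False all rates are multiplied by aid_null_multiplier.
    indel_rate : per-bp probability of a single-base indel (default off).
    spectrum_weights : 4x4 non-negative matrix, zero diagonal; each row is
        renormalised over the three non-identity bases.
    """

    mu_background: float = 8e-4
    hotspot_multiplier: float = 8.0
    aid_active: bool = True
    aid_null_multiplier: float = 0.02
    indel_rate: float = 0.0
    spectrum_weights: np.ndarray = field(default_factory=uniform_spectrum)

    def __post_init__(self) -> None:
        if self.mu_background < 0:
            raise ValueError("mu_background must be >= 0")
        if self.hotspot_multiplier < 1:
            raise ValueError("hotspot_multiplier must be >= 1")
        if not 0 <= self.aid_null_multiplier <= 1:
            raise ValueError("aid_null_multiplier must be in [0,1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        w = np.asarray(self.spectrum_weights, dtype=float)
        if w.shape != (4, 4) or (w < 0).any() or np.diag(w).any():
            raise ValueError(
                "spectrum_weights must be 4x4 non-negative with zero diagonal"
            )
        object.__setattr__(self, "spectrum_weights", w)

    def effective_mu(self) -> float:
        return self.mu_background * (
            1.0 if self.aid_active else self.aid_null_multiplier
        )


@dataclass
class CloneSet:
    """Simulated clones of one condition, FASTA-writable."""

    reference: ReferenceSequence
    clones: list[tuple[str, str]]  # (clone_id, sequence)
    params: SHMParams

    def __len__(self) -> int:
        return len(self.clones)


def expected_hotspot_fraction(n_hotspot: int, n_total: int, h: float) -> float:
    """Closed-form expected fraction of substitutions at hotspot positions.

    With per-site rate mu at n - n_h ordinary sites and h*mu at n_h hotspot
    sites, the expected share of substitutions landing on hotspots is
    n_h*h / (n_h*h + n - n_h), independent of mu.
    """
    return n_hotspot * h / (n_hotspot * h + n_total - n_hotspot)


def generate_reference(length: int, gc: float, seed: int) -> ReferenceSequence:
    """Random reference amplicon with i.i.d. bases at the given GC fraction."""
    if length < 4:
        raise ValueError("length must be >= 4")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(list(BASES), size=length, p=probs))
    return ReferenceSequence(id=f"ref_L{length}_seed{seed}", seq=seq)


def simulate_clones(
    ref: ReferenceSequence, params: SHMParams, n_clones: int, seed: int
) -> CloneSet:
    """Mutate ``n_clones`` independent copies of the reference.

    Each site substitutes with probability mu (h*mu at hotspots), attenuated
    by aid_null_multiplier when AID is inactive; the substituted base is
    drawn from the reference base's spectrum row. Single-base indels occur
    at ``indel_rate`` per bp (deletion or insertion of a random base, 50/50).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(ref)
    labels = hotspot_labels(ref)
    is_hot = np.array([lab != "none" for lab in labels])
    mu = params.effective_mu()
    site_rate = np.where(is_hot, mu * params.hotspot_multiplier, mu)
    site_rate = np.minimum(site_rate, 1.0)

    # per-base alternative distributions from the spectrum matrix
    alt_bases: list[list[str]] = []
    alt_probs: list[np.ndarray] = []
    for b in BASES:
        row = params.spectrum_weights[_BASE_INDEX[b]].copy()
        alts = [x for x in BASES if x != b]
        w = np.array([row[_BASE_INDEX[x]] for x in alts], dtype=float)
        if w.sum() == 0:
            w = np.ones(3)
        alt_bases.append(alts)
        alt_probs.append(w / w.sum())

    ref_arr = np.array(list(ref.seq))
    ref_idx = np.array([_BASE_INDEX[b] for b in ref.seq])
    clones: list[tuple[str, str]] = []
    for k in range(n_clones):
        hit = rng.random(n) < site_rate
        bases = ref_arr.copy()
        for pos in np.flatnonzero(hit):
            i = ref_idx[pos]
            bases[pos] = rng.choice(alt_bases[i], p=alt_probs[i])
        if params.indel_rate > 0:
            out: list[str] = []
            for pos in range(n):
                if rng.random() < params.indel_rate:
                    if rng.random() < 0.5:
                        continue  # single-base deletion
                    out.append(str(rng.choice(list(BASES))))  # insertion before
                out.append(bases[pos])
            seq = "".join(out)
        else:
            seq = "".join(bases)
        clones.append((f"{ref.id}|clone{k:03d}", seq))
    return CloneSet(reference=ref, clones=clones, params=params)


@dataclass(frozen=True)
class PlantedDomain:
    """A planted enriched interval in bin coordinates (half-open).

    ``enrichment`` is either one multiplier or a per-condition mapping.
    """

    chrom: str
    start_bin: int
    end_bin: int
    enrichment: float | Mapping[str, float]

    def multiplier(self, condition: str | None) -> float:
        if isinstance(self.enrichment, Mapping):
            if condition is None:
                raise ValueError(
                    f"domain {self.chrom}:{self.start_bin}-{self.end_bin} has "
                    "per-condition enrichment; a condition name is required"
                )
            m = float(self.enrichment[condition])
        else:
            m = float(self.enrichment)
        if m <= 0:
            raise ValueError("enrichment multipliers must be > 0")
        return m


@dataclass
class PlantedDomainSpec:
    """Background count model plus planted domains for track simulation."""

    domains: list[PlantedDomain]
    background_mean: float = 20.0
    dispersion: float = 100.0  # NB size parameter; inf => Poisson

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def validate_against(self, genome: GenomeSpec) -> None:
        per_chrom: dict[str, list[PlantedDomain]] = {}
        for d in self.domains:
            if d.chrom not in genome:
                raise ValueError(f"planted domain on unknown chromosome {d.chrom!r}")
            if not 0 <= d.start_bin < d.end_bin <= genome.length_of(d.chrom):
                raise ValueError(
                    f"planted domain {d.chrom}:{d.start_bin}-{d.end_bin} out of bounds"
                )
            per_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in per_chrom.items():
            ds = sorted(ds, key=lambda d: d.start_bin)
            for prev, nxt in zip(ds, ds[1:]):
                if nxt.start_bin < prev.end_bin:
                    raise ValueError(f"overlapping planted domains on {chrom}")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_binding_tracks(
    genome: GenomeSpec,
    plan: PlantedDomainSpec,
    seed: int,
    condition: str | None = None,
) -> tuple[BinnedTrack, BinnedTrack, AnnotationSet]:
    """Draw (chip, input, truth) for one condition.

    Input counts are negative binomial around ``background_mean``; ChIP bin
    means are multiplied by the planted enrichment inside domains. The truth
    annotation records domains whose multiplier exceeds 1 for the condition,
    in bp coordinates.
    """
    plan.validate_against(genome)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    truth: list[Interval] = []
    for chrom, n in zip(genome.chromosomes, genome.lengths):
        mean_chip = np.full(n, plan.background_mean, dtype=float)
        for d in plan.domains:
            if d.chrom != chrom:
                continue
            m = d.multiplier(condition)
            mean_chip[d.start_bin : d.end_bin] *= m
            if m > 1:
                truth.append(
                    Interval(
                        chrom,
                        d.start_bin * genome.bin_size,
                        d.end_bin * genome.bin_size,
                        name=f"planted_x{m:g}",
                    )
                )
        chip[chrom] = _nb_counts(rng, mean_chip, plan.dispersion)
        inp[chrom] = _nb_counts(
            rng, np.full(n, plan.background_mean, dtype=float), plan.dispersion
        )
    return (
        BinnedTrack(genome, chip),
        BinnedTrack(genome, inp),
        AnnotationSet(truth),
    )


# --------------------------------------------------------------------------
# Fixture sets: everything the downstream stages consume, from one config.


@dataclass
class FixtureConfig:
    """Fully-specified fixture generation: SHM conditions and binding plan.

    The defaults describe the study design being emulated: a ~565 bp V-region
    with a stimulated condition mutating at 4.5x the control rate, an
    AID-null condition with the stimulated exposure but attenuated rates, and
    two binding conditions sharing constitutive lamina domains while the Ig
    variable clusters drop threefold (canyons) next to compensating mesas.
    """

    seed: int = 0
    ref_length: int = 565
    ref_gc: float = 0.5
    n_clones: int = 30
    shm_conditions: dict[str, SHMParams] = field(default_factory=dict)
    genome: GenomeSpec | None = None
    plan: PlantedDomainSpec | None = None
    binding_conditions: tuple[str, str] = ("control", "shm_induced")
    ig_clusters: AnnotationSet | None = None


def default_fixture_config(seed: int = 0) -> FixtureConfig:
    """The default study-like fixture layout."""
    control_mu = 8e-4
    induction = 4.5
    shm_conditions = {
        "control": SHMParams(mu_background=control_mu),
        "stimulated": SHMParams(mu_background=control_mu * induction),
        "aid_null": SHMParams(
            mu_background=control_mu * induction, aid_active=False
        ),
    }
    genome = GenomeSpec(
        chromosomes=("chr1", "chr2", "chr3", "chr4"),
        lengths=(500, 500, 500, 500),
        bin_size=10_000,
    )
    drop = 3.0  # threefold canyon at each Ig cluster
    lad, canyon_b = 4.0, 4.0 / 3.0
    # mesas sized so both conditions carry the same expected excess signal
    mesa_b = 1.0 + (lad - canyon_b)
    both = {"control": lad, "shm_induced": lad}
    canyon = {"control": lad, "shm_induced": canyon_b}
    mesa = {"control": 1.0, "shm_induced": mesa_b}
    plan = PlantedDomainSpec(
        domains=[
            PlantedDomain("chr1", 50, 70, both),
            PlantedDomain("chr1", 200, 220, canyon),  # IGH
            PlantedDomain("chr1", 222, 242, mesa),
            PlantedDomain("chr2", 150, 170, canyon),  # IGK
            PlantedDomain("chr2", 172, 192, mesa),
            PlantedDomain("chr2", 300, 320, both),
            PlantedDomain("chr3", 100, 120, canyon),  # IGL
            PlantedDomain("chr3", 122, 142, mesa),
            PlantedDomain("chr4", 250, 270, both),
        ],
        background_mean=20.0,
        dispersion=100.0,
    )
    bs = genome.bin_size
    ig = AnnotationSet(
        [
            Interval("chr1", 200 * bs, 220 * bs, "IGHV"),
            Interval("chr2", 150 * bs, 170 * bs, "IGKV"),
            Interval("chr3", 100 * bs, 120 * bs, "IGLV"),
        ]
    )
    assert drop == lad / canyon_b
    return FixtureConfig(
        seed=seed,
        shm_conditions=shm_conditions,
        genome=genome,
        plan=plan,
        ig_clusters=ig,
    )


def _subseed(seed: int, key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(key,))


def write_fixture_set(config: FixtureConfig, out_dir: str | Path) -> list[Path]:
    """Write the complete fixture set; byte-identical for identical configs.

    Emits reference.fasta, clones_<cond>.fasta per SHM condition,
    chip_/input_<cond>.bedGraph per binding condition, truth_<cond>.bed,
    igv_clusters.bed and manifest.tsv (per-file seeds and sha256).
    """
    from . import io as lgio  # local import: io depends on genome only

    if not config.shm_conditions or config.genome is None or config.plan is None:
        config = replace(
            default_fixture_config(config.seed),
            seed=config.seed,
            ref_length=config.ref_length,
            ref_gc=config.ref_gc,
            n_clones=config.n_clones,
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[tuple[Path, int | None]] = []

    ref_seed = int(_subseed(config.seed, 0).generate_state(1)[0] % 2**31)
    ref = generate_reference(config.ref_length, config.ref_gc, ref_seed)
    ref_path = out / "reference.fasta"
    lgio.write_fasta(ref_path, [(ref.id, ref.seq)])
    written.append((ref_path, ref_seed))

    for i, (cond, params) in enumerate(sorted(config.shm_conditions.items())):
        s = int(_subseed(config.seed, 10 + i).generate_state(1)[0] % 2**31)
        clones = simulate_clones(ref, params, config.n_clones, s)
        path = out / f"clones_{cond}.fasta"
        lgio.write_fasta(path, clones.clones)
        written.append((path, s))

    for i, cond in enumerate(config.binding_conditions):
        s = int(_subseed(config.seed, 100 + i).generate_state(1)[0] % 2**31)
        chip, inp, truth = simulate_binding_tracks(
            config.genome, config.plan, s, condition=cond
        )
        p_chip = out / f"chip_{cond}.bedGraph"
        p_inp = out / f"input_{cond}.bedGraph"
        p_truth = out / f"truth_{cond}.bed"
        lgio.write_bedgraph(p_chip, chip)
        lgio.write_bedgraph(p_inp, inp)
        lgio.write_bed(p_truth, truth)
        written += [(p_chip, s), (p_inp, s), (p_truth, s)]

    ig_path = out / "igv_clusters.bed"
    lgio.write_bed(ig_path, config.ig_clusters)
    written.append((ig_path, None))

    genome_path = out / "genome.json"
    genome_path.write_text(
        json.dumps(
            {
                "chromosomes": list(config.genome.chromosomes),
                "lengths": list(config.genome.lengths),
                "bin_size": config.genome.bin_size,
            },
            indent=2,
        )
        + "\n"
    )
    written.append((genome_path, None))

    manifest = out / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("file\tseed\tsha256\n")
        for path, s in written:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            fh.write(f"{path.name}\t{'' if s is None else s}\t{digest}\n")
    return [p for p, _ in written] + [manifest]
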