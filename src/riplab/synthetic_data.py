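"""Seeded generators for every pipeline input, with recorded ground truth.

Four generators emulate the data the analysis stages consume:

* :func:`simulate_ripseq` — gene-level read counts for an Input library, an
  experimental IP and a mock IP, negative-binomially distributed around
  expected abundances, with a planted subset of enriched target genes and
  the five named control transcripts (act5C, orb2, tub56D enriched positive
  controls; 28S and RplP0 unenriched negative controls).
* :func:`simulate_courtship` — per-male courtship bout logs for a naive and
  a trained group, total courtship time Beta-distributed around the group
  mean courtship index.
* :func:`simulate_western` — dilution-series densitometry tables with
  multiplicative lognormal noise on both signal channels.
* :func:`simulate_utr` — background 3'UTR sequence with motifs planted at
  known non-overlapping positions and the background rejection-screened to
  contain no other occurrence of any configured motif.

All generators take a seeded config and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cpe_scan import DEFAULT_MOTIFS, MotifSet, scan_motifs
from .errors import ConfigurationError, GenerationError

__all__ = [
    "BehaviorSimConfig",
    "RipSimConfig",
    "RipTruth",
    "UtrSimConfig",
    "WesternSimConfig",
    "simulate_courtship",
    "simulate_ripseq",
    "simulate_utr",
    "simulate_western",
    "POSITIVE_CONTROLS",
    "NEGATIVE_CONTROLS",
]

POSITIVE_CONTROLS = ("orb2", "act5C", "tub56D")
NEGATIVE_CONTROLS = ("28S", "RplP0")


# --------------------------------------------------------------------------
# RIP-seq counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RipSimConfig:
    """Design of a three-library RIP-seq simulation.

    Baseline gene abundances are lognormal; IP expected abundance is
    baseline times ``target_enrichment_ip`` for planted targets and
    ``control_enrichment`` for the positive controls, then renormalized to
    the IP library size.  Counts are negative binomial with
    variance = mean + dispersion * mean^2 (Poisson at dispersion 0).
    """

    n_genes: int = 5000
    n_targets: int = 500
    target_enrichment_ip: float = 4.0
    control_enrichment: float = 2.0
    library_sizes: tuple[int, int, int] = (1_000_000, 1_000_000, 1_000_000)
    dispersion: float = 0.02
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    biotype_fractions: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not (0 <= self.n_targets <= self.n_genes - len(POSITIVE_CONTROLS) - len(NEGATIVE_CONTROLS)):
            raise ConfigurationError(
                "n_targets must satisfy n_targets + 5 controls <= n_genes"
            )
        if self.target_enrichment_ip < 1 or self.control_enrichment < 1:
            raise ConfigurationError(
                "target_enrichment_ip and control_enrichment must be >= 1"
            )
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ConfigurationError("library_sizes must be three positive integers")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be >= 0")
        if not (0 <= self.biotype_fractions <= 1):
            raise ConfigurationError("biotype_fractions must be in [0, 1]")


@dataclass(frozen=True)
class RipTruth:
    """Ground truth of a RIP-seq simulation: planted targets and control roles."""

    target_ids: frozenset[str]
    control_ids: dict[str, str] = field(hash=False)

    @property
    def positive_control_ids(self) -> frozenset[str]:
        return frozenset(self.control_ids[r] for r in POSITIVE_CONTROLS)

    @property
    def negative_control_ids(self) -> frozenset[str]:
        return frozenset(self.control_ids[r] for r in NEGATIVE_CONTROLS)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion*mean^2; Poisson at 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_ripseq(config: RipSimConfig) -> tuple[pd.DataFrame, RipTruth]:
    """Three-library count matrix plus the planted truth.

    Returns a DataFrame indexed by gene id with columns ``biotype``,
    ``input``, ``ip``, ``mock_ip``, and a :class:`RipTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_ctrl = len(POSITIVE_CONTROLS) + len(NEGATIVE_CONTROLS)

    control_ids = dict(
        zip(POSITIVE_CONTROLS + NEGATIVE_CONTROLS, POSITIVE_CONTROLS + NEGATIVE_CONTROLS)
    )
    other_ids = [f"g{i:05d}" for i in range(n - n_ctrl)]
    gene_ids = list(POSITIVE_CONTROLS) + list(NEGATIVE_CONTROLS) + other_ids

    # Biotypes: positive controls and RplP0 are protein-coding; 28S is rRNA.
    biotype = pd.Series("protein_coding", index=gene_ids, name="biotype")
    biotype.loc["28S"] = "other"
    n_other = len(other_ids)
    is_coding = rng.random(n_other) < config.biotype_fractions
    biotype.loc[other_ids] = np.where(is_coding, "protein_coding", "other")

    # Targets drawn among protein-coding non-control genes.
    coding_pool = [g for g, c in zip(other_ids, is_coding) if c]
    if config.n_targets > len(coding_pool):
        raise ConfigurationError(
            "n_targets exceeds available protein-coding non-control genes; "
            "raise n_genes or biotype_fractions"
        )
    target_ids = sorted(
        rng.choice(coding_pool, size=config.n_targets, replace=False)
    )

    baseline = rng.lognormal(
        mean=config.baseline_log_mean, sigma=config.baseline_log_sd, size=n
    )
    abundance = pd.Series(baseline, index=gene_ids)

    enrichment = pd.Series(1.0, index=gene_ids)
    enrichment.loc[target_ids] = config.target_enrichment_ip
    enrichment.loc[list(POSITIVE_CONTROLS)] = config.control_enrichment

    def expected(rel: pd.Series, lib: int) -> np.ndarray:
        return (rel / rel.sum()).to_numpy() * lib

    lib_input, lib_ip, lib_mock = config.library_sizes
    counts = pd.DataFrame(
        {
            "biotype": biotype,
            "input": _nb_counts(rng, expected(abundance, lib_input), config.dispersion),
            "ip": _nb_counts(
                rng, expected(abundance * enrichment, lib_ip), config.dispersion
            ),
            "mock_ip": _nb_counts(rng, expected(abundance, lib_mock), config.dispersion),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = RipTruth(target_ids=frozenset(target_ids), control_ids=control_ids)
    return counts, truth


# --------------------------------------------------------------------------
# Courtship bout logs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorSimConfig:
    """Two-group courtship simulation: naive vs trained males.

    Per-male courtship index is Beta-distributed with the group mean and a
    common concentration; the male's total courtship time is emitted as a
    single bout at a uniformly placed offset (the courtship index depends
    only on total time, so bout microstructure is not modeled).
    ``ci_concentration=inf`` gives noise-free indices at the group mean.
    """

    n_per_group: int = 20
    observation_s: float = 300.0
    ci_mean_naive: float = 0.6
    ci_mean_trained: float = 0.3
    ci_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be positive")
        if self.observation_s <= 0:
            raise ConfigurationError("observation_s must be > 0")
        for name in ("ci_mean_naive", "ci_mean_trained"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.ci_concentration <= 0:
            raise ConfigurationError("ci_concentration must be > 0")


def simulate_courtship(config: BehaviorSimConfig):
    """Bout logs for ``n_per_group`` naive and trained males."""
    from .behavior_stats import CourtshipObservation

    rng = np.random.default_rng(config.seed)
    observations: list[CourtshipObservation] = []
    for group, mean in (
        ("naive", config.ci_mean_naive),
        ("trained", config.ci_mean_trained),
    ):
        if np.isinf(config.ci_concentration):
            cis = np.full(config.n_per_group, mean)
        elif mean in (0.0, 1.0):
            cis = np.full(config.n_per_group, mean)
        else:
            cis = rng.beta(
                mean * config.ci_concentration,
                (1.0 - mean) * config.ci_concentration,
                size=config.n_per_group,
            )
        for i, ci in enumerate(cis):
            duration = float(ci) * config.observation_s
            if duration <= 0:
                bouts: list[tuple[float, float]] = []
            elif duration >= config.observation_s:
                bouts = [(0.0, config.observation_s)]
            else:
                start = float(rng.uniform(0.0, config.observation_s - duration))
                bouts = [(start, start + duration)]
            observations.append(
                CourtshipObservation(
                    male_id=f"{group}_{i:03d}",
                    group=group,
                    bouts=bouts,
                    observation_s=config.observation_s,
                )
            )
    return observations


# --------------------------------------------------------------------------
# Dilution-series densitometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WesternSimConfig:
    """Dilution-series immunoblot simulation for two genotypes.

    Each replicate loads the dilution ladder ``loads``; the chemiluminescent
    signal is true_level * load and the total-protein signal is load, both
    multiplied by unit-mean lognormal noise with coefficient of variation
    ``cv``.  Default true levels put the mutant at ~1/3 of wild type, the
    regime of a synaptic-fraction depletion.
    """

    true_level_wt: float = 1.0
    true_level_mut: float = 1.0 / 3.0
    loads: tuple[float, ...] = (1 / 2, 1 / 4, 1 / 6)
    cv: float = 0.1
    n_replicates: int = 5
    fraction: str = "P2-synaptic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_level_wt <= 0 or self.true_level_mut <= 0:
            raise ConfigurationError("true levels must be > 0")
        if not self.loads or any(l <= 0 for l in self.loads):
            raise ConfigurationError("loads must be strictly positive")
        if any(l > 1 for l in self.loads):
            raise ConfigurationError("relative loads must be in (0, 1]")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_western(config: WesternSimConfig) -> pd.DataFrame:
    """Densitometry table: one row per lane.

    Columns: genotype, fraction, replicate, lane, relative_load,
    chemi_signal, total_protein_signal.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for genotype, level in (("wt", config.true_level_wt), ("mut", config.true_level_mut)):
        for rep in range(1, config.n_replicates + 1):
            chemi_noise = _lognormal_noise(rng, config.cv, len(config.loads))
            total_noise = _lognormal_noise(rng, config.cv, len(config.loads))
            for lane, (load, cn, tn) in enumerate(
                zip(config.loads, chemi_noise, total_noise), start=1
            ):
                rows.append(
                    {
                        "genotype": genotype,
                        "fraction": config.fraction,
                        "replicate": rep,
                        "lane": lane,
                        "relative_load": load,
                        "chemi_signal": level * load * cn,
                        "total_protein_signal": load * tn,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# 3'UTR sequences with planted motifs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UtrSimConfig:
    """Background 3'UTR with motifs planted at known positions.

    ``planted`` lists (motif, count) pairs; the background is drawn with the
    given GC fraction and rejection-screened so the final sequence contains
    no occurrence of any motif in ``screen_motifs`` besides the planted
    ones.
    """

    length: int = 1000
    planted: tuple[tuple[str, int], ...] = ()
    gc_background: float = 0.4
    screen_motifs: MotifSet = DEFAULT_MOTIFS
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError("length must be positive")
        if not (0.0 <= self.gc_background <= 1.0):
            raise ConfigurationError("gc_background must be in [0, 1]")
        total = 0
        for motif, count in self.planted:
            if count < 0:
                raise ConfigurationError(f"negative count for motif {motif!r}")
            if set(motif.upper()) - set("ACGT"):
                raise ConfigurationError(
                    f"planted motif {motif!r} must be a literal A/C/G/T string"
                )
            total += count * len(motif)
        if total > self.length:
            raise ConfigurationError(
                f"planted motifs need {total} nt but length is {self.length}"
            )


def _place_motifs(
    rng: np.random.Generator,
    length: int,
    instances: Sequence[str],
    max_attempts: int,
) -> list[tuple[int, str]]:
    """Uniform non-overlapping placements, by rejection sampling."""
    for _ in range(max_attempts):
        placements: list[tuple[int, str]] = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for motif in instances:
            start = int(rng.integers(0, length - len(motif) + 1))
            end = start + len(motif)
            if any(s < end and start < e for s, e in occupied):
                ok = False
                break
            occupied.append((start, end))
            placements.append((start, motif))
        if ok:
            return sorted(placements)
    raise GenerationError(
        f"could not place {len(instances)} motifs without overlap in "
        f"{max_attempts} attempts; increase length"
    )


def simulate_utr(config: UtrSimConfig) -> tuple[str, list[tuple[int, str]]]:
    """A sequence containing each planted motif exactly its requested count.

    Returns the sequence and the planted (0-based start, motif) pairs.  The
    full sequence is re-scanned with the screen motif set after assembly;
    if background plus junctions create any extra occurrence, the background
    is resampled (bounded by ``max_attempts``).
    """
    rng = np.random.default_rng(config.seed)
    instances = [m.upper() for m, c in config.planted for _ in range(c)]

    gc = config.gc_background
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    letters = np.array(list("ACGT"))

    already = set(config.screen_motifs.all_patterns())
    planted_patterns = tuple(
        dict.fromkeys(m for m, c in config.planted if c > 0 and m not in already)
    )
    screen = MotifSet(
        canonical=config.screen_motifs.canonical + planted_patterns,
        noncanonical=config.screen_motifs.noncanonical,
    )

    def assemble():
        placements = (
            _place_motifs(rng, config.length, instances, config.max_attempts)
            if instances
            else []
        )
        mask = np.zeros(config.length, dtype=bool)
        seq = rng.choice(letters, size=config.length, p=probs)
        for start, motif in placements:
            seq[start : start + len(motif)] = list(motif)
            mask[start : start + len(motif)] = True
        return placements, mask, seq

    placements, planted_mask, seq = assemble()
    expected_starts = {start for start, _ in placements}

    # Repair loop: resample the background letters inside any unplanted
    # occurrence; when two adjacent planted motifs jointly spell a screened
    # motif (no background inside the span), redraw the whole layout.
    for _ in range(config.max_attempts):
        offending = [
            h for h in scan_motifs("".join(seq), screen)
            if h.start not in expected_starts
        ]
        if not offending:
            return "".join(seq), placements
        redraw = False
        for hit in offending:
            span = np.arange(hit.start, hit.end)
            free = span[~planted_mask[span]]
            if free.size == 0:
                intervals = {
                    (s, s + len(m))
                    for s, m in placements
                    if s < hit.end and hit.start < s + len(m)
                }
                if len(intervals) <= 1:
                    raise GenerationError(
                        f"planted motifs themselves contain an unplanted "
                        f"occurrence of {hit.pattern!r} at {hit.start}; "
                        "choose non-nested motifs"
                    )
                redraw = True
                break
            seq[free] = rng.choice(letters, size=free.size, p=probs)
        if redraw:
            placements, planted_mask, seq = assemble()
            expected_starts = {start for start, _ in placements}
    raise GenerationError(
        f"background screening failed after {config.max_attempts} attempts; "
        "lower gc_background or increase length"
    )
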