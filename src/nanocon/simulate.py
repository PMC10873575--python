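"""Synthetic nanopore 5mC datasets with controlled class structure.

The generator emulates the statistical structure the detector relies on:
methylation perturbs the ionic current in a window around the central
cytosine, so positive instances receive a configurable mean-current shift
(``delta``, in units of the per-base noise) on the ``2w + 1`` positions
centred on the cytosine; motifs follow the CpG / CHG / CHH context grammar
(H = A, C or T); and the positive:negative ratio is a free parameter
spanning the imbalance regimes seen in real methylomes (~0.02 for sparse
plant genomes up to ~1.85 for CpG-rich human data).

Per-base current means sit on a fixed base-level table (A: 0.5, C: -0.3,
G: 0.3, T: -0.5 — arbitrary documented levels standing in for a pore model)
with Gaussian noise; standard deviations are folded-normal; signal lengths
are shifted-Poisson counts.  ``effect_tracks`` confines the class signal to
chosen tracks, which gives ablation experiments a ground truth (if only the
means carry signal, masking the means must hurt).

Everything is driven by one seed and is byte-reproducible, including the
TSV files written through :mod:`nanocon.feature_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .feature_io import (CENTER, MOTIF_LEN, BisulfiteSiteRecord,
                         MethylInstance)

__all__ = ["SimConfig", "BASE_LEVELS", "simulate_motif", "simulate_instance",
           "simulate_dataset", "simulate_bisulfite_report"]

# fixed per-base current levels (normalized units); documented stand-in for
# a real pore model
BASE_LEVELS = {"A": 0.5, "C": -0.3, "G": 0.3, "T": -0.5, "N": 0.0}

_CONTEXTS = ("CpG", "CHG", "CHH")
_H = "ACT"  # "H" = any base but G


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic dataset."""

    n_instances: int = 1000
    proportion: float = 0.25       # positives per negative
    context: str = "mixed"         # CpG | CHG | CHH | mixed
    delta: float = 3.0             # mean-current shift on methylated instances
    effect_width: int = 2          # positions each side of center affected
    noise_sigma: float = 1.0       # per-base current noise SD
    len_rate: float = 8.0          # mean extra signal points per base
    seed: int = 0
    effect_tracks: frozenset[str] = frozenset({"means"})

    def __post_init__(self) -> None:
        if self.n_instances < 2:
            raise ValueError("n_instances must be >= 2")
        if self.proportion <= 0:
            raise ValueError("proportion must be positive")
        if self.context not in (*_CONTEXTS, "mixed"):
            raise ValueError(f"context must be one of {_CONTEXTS} or 'mixed'")
        if not 0 <= self.effect_width <= 6:
            raise ValueError("effect_width must be in [0, 6]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        unknown = set(self.effect_tracks) - {"means", "stds", "lens"}
        if unknown:
            raise ValueError(f"unknown effect tracks: {sorted(unknown)}")
        object.__setattr__(self, "effect_tracks", frozenset(self.effect_tracks))

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["effect_tracks"] = sorted(self.effect_tracks)
        return d


def simulate_motif(context: str, rng: np.random.Generator) -> str:
    """Draw a 13-base motif whose center obeys the given cytosine context.

    Position 6 is always C.  CpG forces G at 7; CHG forces H at 7 and G at
    8; CHH forces H at 7 and 8; ``mixed`` picks a context uniformly.
    """
    if context == "mixed":
        context = _CONTEXTS[rng.integers(len(_CONTEXTS))]
    bases = [ "ACGT"[i] for i in rng.integers(0, 4, size=MOTIF_LEN) ]
    bases[CENTER] = "C"
    if context == "CpG":
        bases[CENTER + 1] = "G"
    elif context == "CHG":
        bases[CENTER + 1] = _H[rng.integers(3)]
        bases[CENTER + 2] = "G"
    elif context == "CHH":
        bases[CENTER + 1] = _H[rng.integers(3)]
        bases[CENTER + 2] = _H[rng.integers(3)]
    return "".join(bases)


def simulate_instance(motif: str, label: int, cfg: SimConfig,
                      rng: np.random.Generator,
                      chrom: str = "sim1", pos: int = 0,
                      read_id: str = "read0") -> MethylInstance:
    """Draw one instance's signal tracks conditional on its label.

    Means are ``N(mu(base) + label * delta * in_window, noise_sigma)``;
    stds are folded-normal ``|N(0, 0.5)| + 0.1``; lens are
    ``1 + Poisson(len_rate)``.  Each track receives the class shift only if
    listed in ``effect_tracks``.
    """
    in_window = np.abs(np.arange(MOTIF_LEN) - CENTER) <= cfg.effect_width
    shift = label * cfg.delta * in_window
    mu = np.array([BASE_LEVELS[b] for b in motif])
    means = rng.normal(mu, cfg.noise_sigma)
    if "means" in cfg.effect_tracks:
        means = means + shift
    stds = np.abs(rng.normal(0.0, 0.5, size=MOTIF_LEN)) + 0.1
    if "stds" in cfg.effect_tracks:
        stds = stds + np.abs(shift)
    lens = 1 + rng.poisson(cfg.len_rate, size=MOTIF_LEN)
    if "lens" in cfg.effect_tracks:
        lens = np.maximum(lens + np.round(shift).astype(int), 1)
    return MethylInstance(
        chrom=chrom, pos=pos, strand="+", read_id=read_id, motif=motif,
        means=tuple(means), stds=tuple(stds),
        lens=tuple(int(l) for l in lens), label=label)


def simulate_dataset(cfg: SimConfig) -> tuple[list[MethylInstance], dict]:
    """Generate a labeled dataset plus a manifest of the settings used.

    Class counts follow ``n_pos = round(n * p / (1 + p))`` so the realized
    positive:negative ratio matches ``proportion`` within rounding.  Output
    order is shuffled; instances carry distinct genomic positions so
    site-keyed operations behave.
    """
    n = cfg.n_instances
    n_pos = int(round(n * cfg.proportion / (1.0 + cfg.proportion)))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"proportion {cfg.proportion} yields a single-class dataset at "
            f"n={n} (n_pos={n_pos}, n_neg={n_neg})")
    rng = np.random.default_rng(cfg.seed)
    labels = np.array([1] * n_pos + [0] * n_neg)
    labels = labels[rng.permutation(n)]
    instances = []
    for i, label in enumerate(labels):
        motif = simulate_motif(cfg.context, rng)
        instances.append(simulate_instance(
            motif, int(label), cfg, rng,
            chrom="sim1", pos=100 * (i + 1), read_id=f"read{i}"))
    manifest = {"config": cfg.to_manifest(),
                "n_positive": int(n_pos), "n_negative": int(n_neg)}
    return instances, manifest


TruthState = Literal["methylated", "unmethylated", "ambiguous"]

_TRUTH_RATES = {"methylated": 0.97, "unmethylated": 0.0, "ambiguous": 0.5}


def simulate_bisulfite_report(
        sites: Sequence[tuple[str, int, str, str]],
        rng: np.random.Generator,
        mean_coverage: float = 10.0,
        context: str = "CpG") -> list[BisulfiteSiteRecord]:
    """Draw per-site bisulfite counts from truth states.

    ``sites`` are (chrom, pos, strand, truth) tuples with truth in
    {methylated, unmethylated, ambiguous}.  Coverage is shifted-Poisson
    (``1 + Poisson(mean_coverage - 1)``) so a tail of sites falls below any
    coverage filter; methylated counts are binomial at a truth-dependent
    rate (0.97 / 0.0 / 0.5).
    """
    if mean_coverage < 1:
        raise ValueError("mean_coverage must be >= 1")
    records = []
    for chrom, pos, strand, truth in sites:
        if truth not in _TRUTH_RATES:
            raise ValueError(f"unknown truth state {truth!r}")
        coverage = 1 + rng.poisson(mean_coverage - 1.0)
        count_meth = rng.binomial(coverage, _TRUTH_RATES[truth])
        records.append(BisulfiteSiteRecord(
            chrom=chrom, pos=pos, strand=strand,
            count_meth=int(count_meth),
            count_unmeth=int(coverage - count_meth),
            context=context))
    return records
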