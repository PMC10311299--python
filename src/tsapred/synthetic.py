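"""Seeded generator of multi-cell-type synthetic datasets.

One shared genome with a latent spatial-state segmentation drives both the
nucleotide composition (so sequence features carry state information) and the
per-cell-type peak tracks. The target signal is a known Tanh-linear function
of the engineered features (optionally of neighboring bins, to create context
dependence), smoothed and emitted on a raw score scale so the full
preprocessing pipeline is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess as pp

__all__ = ["SimConfig", "GroundTruth", "FixtureData", "simulate_genome",
           "simulate_peaks", "simulate_target", "make_fixture", "write_fixture"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_chroms():
    return {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000, "chr4": 5_000_000}


def _default_state_rates():
    # rows = latent states (0 speckle-like, 1 interior, 2 lamina-like)
    return {
        "ATAC":     (0.55, 0.22, 0.03),
        "H2A.Z":    (0.25, 0.25, 0.25),   # decoy: state-independent
        "H3K4me1":  (0.45, 0.18, 0.04),
        "H3K4me2":  (0.20, 0.20, 0.20),   # decoy
        "H3K4me3":  (0.15, 0.15, 0.15),   # decoy
        "H3K9me3":  (0.05, 0.20, 0.50),
        "H3K27me3": (0.18, 0.18, 0.18),   # decoy
        "H3K27ac":  (0.22, 0.22, 0.22),   # decoy
        "H3K36me3": (0.30, 0.30, 0.30),   # decoy
    }


def _default_bodies():
    return {
        # conserved target: driven by tracks whose rates are shared across
        # cell types, plus sequence
        "SON": {
            "causal_tracks": {"ATAC": 0.9, "H3K4me1": 0.6},
            "causal_seq_components": {0: 0.8},
            "neighbor_weight": 0.6,
            "neighbor_range": 3,
            "bias": 0.0,
        },
        # variable target: includes a track whose emission rates differ by
        # cell type
        "LMNB": {
            "causal_tracks": {"H3K9me3": 1.0, "ATAC": -0.5},
            "causal_seq_components": {0: -0.7, 1: -0.4},
            "neighbor_weight": 0.6,
            "neighbor_range": 3,
            "bias": 0.0,
        },
    }


@dataclass
class SimConfig:
    chrom_lengths: dict = field(default_factory=_default_chroms)
    bin_size: int = 25_000
    n_states: int = 3
    mean_segment_bins: float = 8.0
    state_gc: tuple = (0.56, 0.46, 0.36)
    # smooth per-bin compositional fields independent of the latent state;
    # only sequence features can see them, so targets that use sequence
    # components cannot be fully proxied by the peak tracks. Both are
    # strand-symmetric (GC level; CpG-dinucleotide density), hence visible
    # to canonical k-mer features.
    gc_jitter_sd: float = 0.015
    gc_jitter_smooth_bins: int = 11
    cpg_boost_max: float = 0.05      # max fraction of bin positions seeded with CG
    cell_types: tuple = ("CT1", "CT2", "CT3")
    tracks: tuple = pp.EPIGENOMIC_TRACKS
    state_rates: dict = field(default_factory=_default_state_rates)
    # per-cell-type state-rate overrides for variable tracks; a cell type
    # not listed falls back to state_rates. Changing the *profile* over
    # states (not just a global scale, which occupancy normalization would
    # cancel) makes the corresponding targets genuinely cell-type-specific.
    variable_tracks: dict = field(default_factory=lambda: {
        "H3K9me3": {
            "CT1": (0.60, 0.05, 0.05),
            "CT2": (0.05, 0.60, 0.05),
            "CT3": (0.05, 0.05, 0.60),
        }})
    occupancy_jitter: float = 0.04
    bodies: dict = field(default_factory=_default_bodies)
    signal_scale: float = 8.0        # raw score = offset + scale * signal
    signal_offset: float = 1.5
    noise_sd: float = 0.05           # on the tanh scale, before raw scaling
    smooth_window: int = 21
    n_components: int = 20
    ks: tuple = (5, 6)
    seed: int = 0

    def validate(self):
        nums = [n for n in (  # at least one odd and one even autosome
            [int(c.replace("chr", "")) for c in self.chrom_lengths
             if c.replace("chr", "").isdigit()])]
        if not any(n % 2 for n in nums) or not any(n % 2 == 0 for n in nums):
            raise ValueError("need at least one odd and one even autosome")
        for tr, rates in self.state_rates.items():
            if any(r < 0 for r in rates):
                raise ValueError(f"negative emission rate for {tr}")


@dataclass
class GroundTruth:
    states: np.ndarray                       # (n_bins,) latent state per bin
    noiseless: dict = field(default_factory=dict)   # (ct, body) -> smoothed target
    causal: dict = field(default_factory=dict)      # body -> {feature: coefficient}


@dataclass
class FixtureData:
    """In-memory synthetic dataset: shared frame + per-cell-type tracks."""

    cfg: SimConfig
    bins: pp.BinTable
    sequences: dict                          # chrom -> str
    seqfeat: pp.SequenceFeatures
    peaks: dict                              # ct -> {track: [(chrom, s, e), ...]}
    epifeat: dict                            # ct -> EpigenomicFeatures (normalized)
    raw_signal: dict                         # (ct, body) -> np.ndarray raw scores
    targets: dict                            # (ct, body) -> TargetTrack
    truth: GroundTruth


# ----------------------------------------------------------------- genome
def simulate_genome(cfg: SimConfig, rng: np.random.Generator):
    """Markov latent-state segmentation + state-conditioned nucleotides.

    Returns (sequences: chrom->str, bins, states per bin).
    """
    bins = pp.make_bins(cfg.chrom_lengths, cfg.bin_size)
    stay = 1.0 - 1.0 / cfg.mean_segment_bins
    states = np.empty(bins.n_bins, dtype=np.int64)
    for chrom in bins.chrom_order:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        s = np.empty(n, dtype=np.int64)
        s[0] = rng.integers(cfg.n_states)
        for i in range(1, n):
            if rng.random() < stay:
                s[i] = s[i - 1]
            else:
                choices = [k for k in range(cfg.n_states) if k != s[i - 1]]
                s[i] = choices[rng.integers(len(choices))]
        states[sl] = s

    def smooth_field(n: int, sd: float) -> np.ndarray:
        """Spatially smooth zero-mean field (isochore-like variation)."""
        raw = rng.normal(0.0, 1.0, size=n)
        k = min(cfg.gc_jitter_smooth_bins, n if n % 2 else n - 1)
        if k < 3:
            return raw * sd
        w = np.hanning(k)
        w /= w.sum()
        den = np.convolve(np.ones(n), w, mode="same")
        sm = np.convolve(raw, w, mode="same") / den
        s = sm.std()
        return sm * (sd / s if s > 0 else 0.0)

    sequences = {}
    for chrom in bins.chrom_order:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        length = int(cfg.chrom_lengths[chrom])
        gc_jit = smooth_field(n, cfg.gc_jitter_sd)
        cpg = cfg.cpg_boost_max * (1.0 + np.clip(smooth_field(n, 1.0), -1, 1)) / 2.0
        parts = []
        for j, i in enumerate(range(sl.start, sl.stop)):
            gc = np.clip(cfg.state_gc[states[i]] + gc_jit[j], 0.2, 0.8)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            draws = rng.choice(4, size=cfg.bin_size, p=p)
            # seed CG dinucleotides at a smoothly varying density (CpG is its
            # own reverse complement, so canonical k-mers see it)
            n_cpg = int(round(cpg[j] * cfg.bin_size / 2))
            if n_cpg > 0:
                pos = rng.choice(cfg.bin_size - 1, size=n_cpg, replace=False)
                draws[pos] = 1      # C
                draws[pos + 1] = 2  # G
            parts.append(_BASES[draws])
        tail = length - n * cfg.bin_size
        if tail > 0:  # trailing partial bin: neutral composition
            parts.append(_BASES[rng.integers(0, 4, size=tail)])
        sequences[chrom] = np.concatenate(parts).tobytes().decode("ascii")
    return sequences, bins, states


# ------------------------------------------------------------------ peaks
def simulate_peaks(cfg: SimConfig, bins: pp.BinTable, states: np.ndarray,
                   cell_type: str, rng: np.random.Generator) -> dict:
    """One interval list per track; occupancy per bin fluctuates around the
    state- and cell-type-specific emission rate."""
    out = {}
    for track in cfg.tracks:
        override = cfg.variable_tracks.get(track, {}).get(cell_type)
        rates = np.asarray(override if override is not None
                           else cfg.state_rates[track], dtype=np.float64)
        intervals = []
        for i in range(bins.n_bins):
            rate = rates[states[i]]
            if rate <= 0:
                continue
            occ = np.clip(rate + rng.normal(0.0, cfg.occupancy_jitter), 0.0, 0.95)
            width = int(round(occ * bins.bin_size))
            if width == 0:
                continue
            off = rng.integers(0, bins.bin_size - width + 1)
            s = int(bins.starts[i]) + int(off)
            intervals.append((str(bins.chroms[i]), s, s + width))
        out[track] = intervals
    return out


# ----------------------------------------------------------------- target
def _neighbor_mean(x: np.ndarray, bins: pp.BinTable, rad: int) -> np.ndarray:
    """Mean of x over bins at distance 1..rad on either side (per chromosome,
    truncated at ends)."""
    out = np.zeros_like(x)
    for chrom in bins.chrom_order:
        sl = bins.chrom_slice(chrom)
        v = x[sl]
        n = len(v)
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for d in range(1, rad + 1):
            acc[d:] += v[:-d]
            cnt[d:] += 1
            acc[:-d] += v[d:]
            cnt[:-d] += 1
        out[sl] = acc / np.maximum(cnt, 1)
    return out


def simulate_target(cfg: SimConfig, body: str, seqfeat: pp.SequenceFeatures,
                    epifeat: pp.EpigenomicFeatures, bins: pp.BinTable,
                    rng: np.random.Generator):
    """Known feature->signal mapping for one cell type and body.

    Returns (raw_score, noiseless_smoothed, causal_coefficients).
    noiseless = tanh(own-bin linear term + neighbor_weight * neighbor mean of
    the same linear combination), then Hanning-smoothed. The raw score is
    offset + scale * (pre-smoothing noiseless + noise), so running it through
    ``build_target`` reproduces the smoothed noiseless target up to noise and
    scaling.
    """
    spec = cfg.bodies[body]
    causal = {}
    lin = np.zeros(bins.n_bins)
    for track, w in spec["causal_tracks"].items():
        if track not in epifeat.tracks:
            raise ValueError(f"causal track {track!r} not among features")
        t = epifeat.tracks.index(track)
        lin = lin + w * (epifeat.values[:, t] - 1.0)
        causal[track] = w
    valid = bins.valid
    for comp, w in spec["causal_seq_components"].items():
        comp = int(comp)
        if comp >= seqfeat.n_components:
            raise ValueError(f"causal sequence component {comp} out of range")
        col = seqfeat.features[:, comp]
        sd = np.nanstd(col[valid])
        z = np.where(np.isfinite(col), col / (sd if sd > 0 else 1.0), 0.0)
        lin = lin + w * z
        causal[f"seq_pc{comp}"] = w
    pre = spec["bias"] + lin + spec["neighbor_weight"] * _neighbor_mean(
        lin, bins, spec["neighbor_range"])
    noiseless = np.tanh(pre)
    smoothed = pp.smooth_track(noiseless, valid, bins, window_len=cfg.smooth_window)
    noisy = noiseless + rng.normal(0.0, cfg.noise_sd, size=len(noiseless))
    raw = cfg.signal_offset + cfg.signal_scale * noisy
    return raw, smoothed, causal


# ---------------------------------------------------------------- fixture
def make_fixture(cfg: SimConfig | None = None) -> FixtureData:
    """Run the three simulators plus preprocessing end to end (in memory)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sequences, bins, states = simulate_genome(cfg, rng)

    def get_seq(chrom, start, end):
        return sequences[chrom][start:end]

    seqfeat = pp.fit_sequence_features(get_seq, bins, ks=cfg.ks,
                                       n_components=cfg.n_components)
    peaks, epifeat = {}, {}
    for ct in cfg.cell_types:
        peaks[ct] = simulate_peaks(cfg, bins, states, ct, rng)
        raw_occ = pp.peak_occupancy(peaks[ct], bins, tracks=cfg.tracks)
        epifeat[ct] = pp.normalize_occupancy(raw_occ, bins.valid)

    truth = GroundTruth(states=states)
    raw_signal, targets = {}, {}
    for ct in cfg.cell_types:
        for body in cfg.bodies:
            raw, smoothed, causal = simulate_target(
                cfg, body, seqfeat, epifeat[ct], bins, rng)
            raw_signal[(ct, body)] = raw
            truth.noiseless[(ct, body)] = smoothed
            truth.causal[body] = causal
            targets[(ct, body)] = pp.build_target(
                raw, np.ones(bins.n_bins, dtype=bool), bins,
                window_len=cfg.smooth_window, cell_type=ct, body=body)
    return FixtureData(cfg=cfg, bins=bins, sequences=sequences, seqfeat=seqfeat,
                       peaks=peaks, epifeat=epifeat, raw_signal=raw_signal,
                       targets=targets, truth=truth)


def write_fixture(fx: FixtureData, outdir) -> None:
    """Write the fixture as FASTA / chrom.sizes / BED / bedGraph / JSON."""
    from . import io as tio
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(fx.sequences, outdir / "genome.fa")
    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for c, ln in fx.cfg.chrom_lengths.items():
            fh.write(f"{c}\t{ln}\n")
    for ct, tracks in fx.peaks.items():
        d = outdir / "peaks" / ct
        d.mkdir(parents=True, exist_ok=True)
        for track, ivs in tracks.items():
            safe = track.replace(".", "_")
            with open(d / f"{safe}.bed", "w") as fh:
                for chrom, s, e in sorted(ivs):
                    fh.write(f"{chrom}\t{s}\t{e}\n")
    for (ct, body), raw in fx.raw_signal.items():
        d = outdir / "signal"
        d.mkdir(exist_ok=True)
        tio.write_bedgraph(raw, fx.bins, d / f"{ct}.{body}.bedGraph")
    gt = {
        "states": fx.truth.states.tolist(),
        "causal": fx.truth.causal,
        "noiseless": {f"{ct}|{body}": np.where(np.isfinite(v), v, None).tolist()
                      for (ct, body), v in fx.truth.noiseless.items()},
        "seed": fx.cfg.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)


def fixture_datasets(fx: FixtureData, body: str, standardized: bool = True) -> dict:
    """CellDataset per cell type for one nuclear body (z-scored features by
    default, matching the training pipeline)."""
    from .train import CellDataset, standardize
    out = {}
    for ct in fx.cfg.cell_types:
        ds = CellDataset(bins=fx.bins, seq=fx.seqfeat.features,
                         epi=fx.epifeat[ct].values, target=fx.targets[(ct, body)],
                         cell_type=ct)
        out[ct] = standardize(ds) if standardized else ds
    return out
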