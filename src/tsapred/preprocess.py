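"""Feature engineering: genomic bins, k-mer sequence features, peak occupancy,
and target-signal scaling/smoothing.

All coordinates are 0-based half-open. The bin table is the universal
coordinate frame: every feature/target matrix is row-aligned to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

DEFAULT_BIN_SIZE = 25_000
DEFAULT_KS = (5, 6)
DEFAULT_N_COMPONENTS = 20
DEFAULT_SMOOTH_WINDOW = 21
DEFAULT_CLIP_QUANTILES = (0.005, 0.995)

EPIGENOMIC_TRACKS = (
    "ATAC",
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9me3",
    "H3K27me3",
    "H3K27ac",
    "H3K36me3",
)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


# --------------------------------------------------------------------- bins
@dataclass
class BinTable:
    """Ordered equal-width genomic bins with a validity mask."""

    chroms: np.ndarray          # str per bin
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    valid: np.ndarray           # bool
    bin_size: int
    chrom_order: tuple = ()

    def __post_init__(self):
        if not self.chrom_order:
            seen = dict.fromkeys(self.chroms.tolist())
            self.chrom_order = tuple(seen)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def index_in_chrom(self) -> np.ndarray:
        out = np.empty(self.n_bins, dtype=np.int64)
        for c in self.chrom_order:
            sl = self.chrom_slice(c)
            out[sl] = np.arange(sl.stop - sl.start)
        return out


def merge_intervals(starts, ends):
    """Merge overlapping/adjacent intervals; returns (starts, ends) sorted."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _coverage_per_bin(starts, ends, n_bins: int, bin_size: int) -> np.ndarray:
    """Bases of the merged intervals falling in each of n_bins regular bins."""
    cov = np.zeros(n_bins, dtype=np.float64)
    limit = n_bins * bin_size
    for s, e in zip(starts, ends):
        s = max(int(s), 0)
        e = min(int(e), limit)
        if e <= s:
            continue
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            cov[b0] += e - s
        else:
            cov[b0] += (b0 + 1) * bin_size - s
            cov[b1] += e - b1 * bin_size
            if b1 > b0 + 1:
                cov[b0 + 1:b1] += bin_size
    return cov


def make_bins(chrom_sizes: dict, bin_size: int = DEFAULT_BIN_SIZE,
              exclude=None, exclude_threshold: float = 0.5) -> BinTable:
    """Tile each chromosome with non-overlapping ``bin_size`` bins.

    The trailing partial bin is dropped. A bin is flagged invalid when its
    overlap with the exclude intervals exceeds ``exclude_threshold`` of the
    bin width.

    Parameters
    ----------
    chrom_sizes : mapping chrom -> length in bp
    exclude : mapping chrom -> (starts, ends) arrays, or list of
        (chrom, start, end) tuples, or None
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    excl: dict = {}
    if exclude is not None:
        if isinstance(exclude, dict):
            items = [(c, s, e) for c, (ss, ee) in exclude.items() for s, e in zip(ss, ee)]
        else:
            items = list(exclude)
        for c, s, e in items:
            excl.setdefault(c, ([], []))
            excl[c][0].append(s)
            excl[c][1].append(e)
        for c in list(excl):
            if c not in chrom_sizes:
                warnings.warn(f"exclude interval on unknown chromosome {c!r}; skipped")
                del excl[c]

    chroms, starts, ends, valid = [], [], [], []
    for chrom, length in chrom_sizes.items():
        n = int(length) // bin_size
        if n == 0:
            continue
        bs = np.arange(n, dtype=np.int64) * bin_size
        ok = np.ones(n, dtype=bool)
        if chrom in excl:
            ms, me = merge_intervals(*excl[chrom])
            cov = _coverage_per_bin(ms, me, n, bin_size)
            ok = cov / bin_size <= exclude_threshold
        chroms.extend([chrom] * n)
        starts.append(bs)
        ends.append(bs + bin_size)
        valid.append(ok)
    return BinTable(
        chroms=np.array(chroms, dtype=object),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        valid=np.concatenate(valid),
        bin_size=bin_size,
        chrom_order=tuple(c for c in chrom_sizes if int(chrom_sizes[c]) // bin_size > 0),
    )


# ------------------------------------------------------------------- k-mers
def _canonical_table(k: int):
    """Map every k-mer code (base-4, A=0..T=3) to its canonical index.

    Canonical form = lexicographic min of the k-mer and its reverse
    complement. Returns (code->canonical-slot array, number of canonical
    k-mers).
    """
    n = 4 ** k
    codes = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    tmp = codes.copy()
    for i in range(k - 1, -1, -1):
        digits[i] = tmp % 4
        tmp //= 4
    # reverse complement: complement digit = 3 - digit, then reverse order
    rc = np.zeros(n, dtype=np.int64)
    for i in range(k):
        rc = rc * 4 + (3 - digits[k - 1 - i])
    canon_code = np.minimum(codes, rc)
    uniq, slot = np.unique(canon_code, return_inverse=True)
    return slot, len(uniq), canon_code


_CANON_CACHE: dict = {}


def canonical_kmer_count(k: int) -> int:
    if k not in _CANON_CACHE:
        _CANON_CACHE[k] = _canonical_table(k)
    return _CANON_CACHE[k][1]


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Canonical k-mer frequency vector of ``sequence``.

    Windows containing non-ACGT symbols are skipped and excluded from the
    denominator. If every window is ambiguous a zero vector is returned with
    a warning.
    """
    if k not in (5, 6):
        raise ValueError(f"k={k} unsupported; expected 5 or 6")
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    if k not in _CANON_CACHE:
        _CANON_CACHE[k] = _canonical_table(k)
    slot, n_canon, _ = _CANON_CACHE[k]

    base = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_win = len(base) - k + 1
    # rolling base-4 code; windows touching an ambiguous base are dropped
    ok = base >= 0
    win_ok = np.ones(n_win, dtype=bool)
    code = np.zeros(n_win, dtype=np.int64)
    mult = 1
    for i in range(k - 1, -1, -1):
        col = base[i:i + n_win]
        code += np.where(col >= 0, col, 0) * mult
        win_ok &= ok[i:i + n_win]
        mult *= 4
    code = code[win_ok]
    out = np.zeros(n_canon, dtype=np.float64)
    if code.size == 0:
        warnings.warn("all k-mer windows contain ambiguous bases; zero vector")
        return out
    counts = np.bincount(slot[code], minlength=n_canon)
    return counts / code.size


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgtN", "TGCAtgcaN")
    return seq.translate(comp)[::-1]


# -------------------------------------------------------- sequence features
@dataclass
class SequenceFeatures:
    """PCA-reduced canonical k-mer frequencies per bin, plus the fitted map."""

    features: np.ndarray            # (n_bins, n_components); NaN rows where invalid
    components: np.ndarray          # (n_components, raw_dim)
    mean: np.ndarray                # (raw_dim,)
    ks: tuple
    n_components: int

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.mean) @ self.components.T

    def save(self, path) -> None:
        np.savez(
            path,
            features=self.features,
            components=self.components,
            mean=self.mean,
            ks=np.asarray(self.ks),
            n_components=self.n_components,
        )

    @classmethod
    def load(cls, path) -> "SequenceFeatures":
        with np.load(path) as z:
            return cls(
                features=z["features"],
                components=z["components"],
                mean=z["mean"],
                ks=tuple(int(k) for k in z["ks"]),
                n_components=int(z["n_components"]),
            )


def kmer_matrix(get_seq, bins: BinTable, ks=DEFAULT_KS,
                max_ambiguous_frac: float = 0.5):
    """Concatenated k-mer frequency matrix for all bins.

    ``get_seq(chrom, start, end)`` returns the bin sequence. Bins with more
    than ``max_ambiguous_frac`` ambiguous bases are flagged.
    """
    dims = [canonical_kmer_count(k) for k in ks]
    mat = np.zeros((bins.n_bins, sum(dims)), dtype=np.float64)
    ambiguous = np.zeros(bins.n_bins, dtype=bool)
    for i in range(bins.n_bins):
        seq = get_seq(str(bins.chroms[i]), int(bins.starts[i]), int(bins.ends[i]))
        n_amb = sum(1 for ch in seq if ch.upper() not in "ACGT")
        if n_amb > max_ambiguous_frac * len(seq):
            ambiguous[i] = True
            continue
        off = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, d in zip(ks, dims):
                mat[i, off:off + d] = kmer_frequencies(seq, k)
                off += d
    return mat, ambiguous


def fit_sequence_features(get_seq, bins: BinTable, ks=DEFAULT_KS,
                          n_components: int = DEFAULT_N_COMPONENTS) -> SequenceFeatures:
    """Fit the k-mer PCA on valid bins and project every bin.

    The transform (components + mean) is persisted inside the returned object
    so new genomes/cell types project into the same space.
    """
    raw, ambiguous = kmer_matrix(get_seq, bins, ks=ks)
    usable = bins.valid & ~ambiguous
    n_use = int(usable.sum())
    if n_use < n_components:
        raise ValueError(f"only {n_use} valid bins for {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(raw[usable])
    feats = np.full((bins.n_bins, n_components), np.nan)
    feats[usable] = (raw[usable] - pca.mean_) @ pca.components_.T
    return SequenceFeatures(
        features=feats,
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        ks=tuple(ks),
        n_components=n_components,
    )


# ------------------------------------------------------------ peak features
@dataclass
class EpigenomicFeatures:
    values: np.ndarray              # (n_bins, n_tracks)
    tracks: tuple
    track_means: np.ndarray | None = None   # set by normalize_occupancy

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


def peak_occupancy(peaks: dict, bins: BinTable, tracks=EPIGENOMIC_TRACKS) -> EpigenomicFeatures:
    """Fraction of each bin covered by (merged) peaks, per track.

    ``peaks[track]`` is a list of (chrom, start, end) intervals. Peaks on
    chromosomes absent from the bin table are skipped with a warning.
    """
    vals = np.zeros((bins.n_bins, len(tracks)), dtype=np.float64)
    for t, track in enumerate(tracks):
        by_chrom: dict = {}
        for chrom, s, e in peaks.get(track, ()):
            if chrom not in bins.chrom_order:
                warnings.warn(f"peak on unknown chromosome {chrom!r} in track {track}; skipped")
                continue
            by_chrom.setdefault(chrom, ([], []))
            by_chrom[chrom][0].append(s)
            by_chrom[chrom][1].append(e)
        for chrom, (ss, ee) in by_chrom.items():
            sl = bins.chrom_slice(chrom)
            n = sl.stop - sl.start
            ms, me = merge_intervals(ss, ee)
            vals[sl, t] = _coverage_per_bin(ms, me, n, bins.bin_size) / bins.bin_size
    return EpigenomicFeatures(values=vals, tracks=tuple(tracks))


def normalize_occupancy(raw: EpigenomicFeatures, valid: np.ndarray) -> EpigenomicFeatures:
    """Divide each track by its genome-wide mean over valid bins.

    Tracks with zero mean are left at zero with a warning.
    """
    means = raw.values[valid].mean(axis=0)
    out = raw.values.copy()
    for t, m in enumerate(means):
        if m > 0:
            out[:, t] /= m
        else:
            warnings.warn(f"track {raw.tracks[t]} has zero genome-wide occupancy; left unnormalized")
    return EpigenomicFeatures(values=out, tracks=raw.tracks, track_means=means)


# ----------------------------------------------------------------- targets
@dataclass
class TargetTrack:
    """Scaled ([-1,1]) and Hanning-smoothed per-bin signal for one cell type
    and one nuclear body."""

    values: np.ndarray
    mask: np.ndarray                # True where a value is defined
    cell_type: str = ""
    body: str = ""
    clip_bounds: tuple = (np.nan, np.nan)

    def unscale(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.clip_bounds
        return (y + 1.0) * 0.5 * (hi - lo) + lo


def hanning_kernel(window_len: int) -> np.ndarray:
    if window_len % 2 != 1:
        raise ValueError("window_len must be odd")
    w = np.hanning(window_len)
    return w / w.sum()


def smooth_track(values: np.ndarray, mask: np.ndarray, bins: BinTable,
                 window_len: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Per-chromosome Hanning smoothing honouring the validity mask.

    At chromosome ends and around masked bins the window is truncated to the
    available valid bins and re-normalized, which keeps constants exact.
    """
    out = np.full_like(values, np.nan, dtype=np.float64)
    for chrom in bins.chrom_order:
        sl = bins.chrom_slice(chrom)
        v = values[sl]
        n = len(v)
        eff = min(window_len, n if n % 2 else n - 1)  # short chromosomes
        if eff < 3:
            res = np.where(mask[sl], v, np.nan)
            out[sl] = res
            continue
        w = hanning_kernel(eff)
        m = mask[sl].astype(np.float64)
        num = np.convolve(np.where(mask[sl], v, 0.0), w, mode="same")
        den = np.convolve(m, w, mode="same")
        ok = mask[sl] & (den > 0)
        res = np.full(len(v), np.nan)
        res[ok] = num[ok] / den[ok]
        out[sl] = res
    return out


def build_target(scores: np.ndarray, mask: np.ndarray, bins: BinTable,
                 window_len: int = DEFAULT_SMOOTH_WINDOW,
                 clip_quantiles=DEFAULT_CLIP_QUANTILES,
                 clip_bounds=None,
                 cell_type: str = "", body: str = "") -> TargetTrack:
    """Quantile-clip, scale to [-1, 1], then Hanning-smooth a binned signal.

    ``mask`` marks bins carrying signal; the returned mask additionally
    requires bin validity. ``clip_bounds`` overrides the quantile-derived
    bounds (e.g. (-1, 1) for signal already on the target scale). A constant
    input maps to 0 with a warning.
    """
    use = mask & bins.valid
    vals = np.asarray(scores, dtype=np.float64)
    if clip_bounds is not None:
        lo, hi = clip_bounds
    else:
        lo, hi = np.quantile(vals[use], clip_quantiles) if use.any() else (0.0, 0.0)
    if hi <= lo:
        warnings.warn("constant/degenerate signal; scaled to 0")
        scaled = np.zeros_like(vals)
        lo, hi = float(lo), float(lo)
    else:
        scaled = (np.clip(vals, lo, hi) - lo) / (hi - lo) * 2.0 - 1.0
    smoothed = smooth_track(scaled, use, bins, window_len=window_len)
    return TargetTrack(
        values=np.where(use, smoothed, np.nan),
        mask=use,
        cell_type=cell_type,
        body=body,
        clip_bounds=(float(lo), float(hi)),
    )
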