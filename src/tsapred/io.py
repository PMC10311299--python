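"""Readers/writers for the standard genomics text formats plus run manifests.

All coordinates are 0-based half-open (BED convention). bigWig input is not
supported in this build (no bigWig library available); convert to bedGraph.
"""

from __future__ import annotations

import hashlib
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import BinTable

__all__ = [
    "read_fasta", "write_fasta", "read_chrom_sizes", "read_intervals",
    "read_bedgraph", "read_signal", "signal_to_bins", "write_bedgraph",
    "file_digest", "write_manifest", "read_manifest",
    "save_dataset", "load_dataset",
]


def read_fasta(path):
    """Returns ``get_seq(chrom, start, end)`` over an indexed FASTA."""
    from pyfaidx import Fasta
    fa = Fasta(str(path))

    def get_seq(chrom: str, start: int, end: int) -> str:
        return str(fa[chrom][start:end])

    return get_seq


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_chrom_sizes(path) -> dict:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            out[parts[0]] = int(parts[1])
    return out


def read_intervals(path, fmt: str | None = None):
    """BED3/BED6/narrowPeak -> list of (chrom, start, end).

    Columns beyond the third are parsed but unused. Raises on malformed
    lines with the line number; unsorted input is accepted (downstream
    operations sort/merge).
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from err
            if e < s:
                raise ValueError(f"{path}:{ln}: end < start")
            out.append((parts[0], s, e))
    return out


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: fewer than 4 bedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: malformed bedGraph record") from err
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if not df.sort_values(["chrom", "start"]).equals(df.reset_index(drop=True)):
        warnings.warn(f"{path}: records not sorted; sorting internally")
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def signal_to_bins(df: pd.DataFrame, bins: BinTable):
    """Coverage-weighted mean of bedGraph records per bin.

    Returns (values, mask); mask is False where a bin has no covering record.
    """
    num = np.zeros(bins.n_bins)
    den = np.zeros(bins.n_bins)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in bins.chrom_order:
            warnings.warn(f"signal on unknown chromosome {chrom!r}; skipped")
            continue
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        bs = bins.bin_size
        for s, e, v in zip(sub["start"].values, sub["end"].values, sub["value"].values):
            s, e = max(int(s), 0), min(int(e), n * bs)
            if e <= s:
                continue
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                ov = min(e, (b + 1) * bs) - max(s, b * bs)
                num[sl.start + b] += ov * v
                den[sl.start + b] += ov
    mask = den > 0
    vals = np.zeros(bins.n_bins)
    vals[mask] = num[mask] / den[mask]
    return vals, mask


def read_signal(path, fmt: str | None = None):
    """Binned-signal reader. bedGraph only; bigWig requires conversion."""
    path = str(path)
    if fmt == "bigWig" or path.endswith((".bw", ".bigWig", ".bigwig")):
        raise NotImplementedError(
            "bigWig input is not supported in this build; convert to bedGraph "
            "(e.g. bigWigToBedGraph)")
    return read_bedgraph(path)


def write_bedgraph(values: np.ndarray, bins: BinTable, path) -> None:
    """Sorted, non-overlapping bedGraph on the bin frame; NaN bins skipped."""
    with open(path, "w") as fh:
        for chrom in bins.chrom_order:
            sl = bins.chrom_slice(chrom)
            for i in range(sl.start, sl.stop):
                v = values[i]
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{bins.starts[i]}\t{bins.ends[i]}\t{v:.10g}\n")


# ------------------------------------------------------------------ manifest
def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, config: dict, seeds: dict,
                   inputs=(), outputs=()) -> Path:
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_manifest(outdir):
    path = Path(outdir) / "manifest.yaml"
    if not path.exists():
        return None
    with open(path) as fh:
        return yaml.safe_load(fh)


def stage_is_complete(outdir, stage: str, inputs=()) -> bool:
    """True when a manifest exists for ``stage`` with matching input digests
    and all recorded outputs are present."""
    m = read_manifest(outdir)
    if m is None or m.get("stage") != stage:
        return False
    for p, digest in m.get("inputs", {}).items():
        if not Path(p).exists() or file_digest(p) != digest:
            return False
    return all(Path(p).exists() for p in m.get("outputs", []))


# ----------------------------------------------------------------- datasets
def save_dataset(ds, outdir) -> None:
    """Persist a CellDataset: TSV tables for inspection plus one npz archive
    that round-trips exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = ds.bins
    pd.DataFrame({
        "chrom": bins.chroms, "start": bins.starts, "end": bins.ends,
        "valid": bins.valid.astype(int),
    }).to_csv(outdir / "bins.tsv", sep="\t", index=False)
    feat = pd.DataFrame({
        "chrom": bins.chroms, "start": bins.starts, "end": bins.ends,
    })
    for j in range(ds.seq.shape[1]):
        feat[f"seq_pc{j}"] = ds.seq[:, j]
    for j in range(ds.epi.shape[1]):
        feat[f"epi{j}"] = ds.epi[:, j]
    feat["target"] = ds.target.values
    feat["target_mask"] = ds.target.mask.astype(int)
    feat.to_csv(outdir / "features.tsv", sep="\t", index=False, float_format="%.10g")
    np.savez(
        outdir / "dataset.npz",
        chroms=np.array([str(c) for c in bins.chroms]),
        starts=bins.starts, ends=bins.ends, valid=bins.valid,
        bin_size=bins.bin_size,
        chrom_order=np.array(list(bins.chrom_order)),
        seq=ds.seq, epi=ds.epi,
        target_values=ds.target.values, target_mask=ds.target.mask,
        clip_bounds=np.asarray(ds.target.clip_bounds, dtype=np.float64),
        cell_type=np.array(ds.cell_type), body=np.array(ds.target.body),
    )


def load_dataset(outdir):
    from .preprocess import TargetTrack
    from .train import CellDataset
    with np.load(Path(outdir) / "dataset.npz", allow_pickle=False) as z:
        bins = BinTable(
            chroms=z["chroms"].astype(object), starts=z["starts"], ends=z["ends"],
            valid=z["valid"], bin_size=int(z["bin_size"]),
            chrom_order=tuple(str(c) for c in z["chrom_order"]),
        )
        target = TargetTrack(
            values=z["target_values"], mask=z["target_mask"],
            cell_type=str(z["cell_type"]), body=str(z["body"]),
            clip_bounds=tuple(z["clip_bounds"]),
        )
        return CellDataset(bins=bins, seq=z["seq"], epi=z["epi"], target=target,
                           cell_type=str(z["cell_type"]))
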