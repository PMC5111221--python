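"""Readers and writers for the package's plain-text formats.

All coordinates on disk are 0-based half-open (BED convention), matching
the in-memory representation.  Every writer prepends ``#``-prefixed
provenance lines (tool version, config hash, seed) which every reader
skips, so outputs round-trip losslessly and reruns with an identical
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .grid import BinGrid
from .profiling import BlacklistRegions, CNProfile, RatioTrack, Segment, call_segments
from .simulate import BinCounts, TruthProfile


def provenance_header(seed: int | None = None, **config) -> str:
    items = {k: config[k] for k in sorted(config)}
    digest = hashlib.sha256(
        json.dumps(items, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    lines = [f"# shallowcn={__version__}", f"# config_sha256={digest}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for k, v in items.items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _write(path, header: str, df: pd.DataFrame, with_columns: bool) -> None:
    buf = _io.StringIO()
    buf.write(header)
    df.to_csv(buf, sep="\t", index=False, header=with_columns)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# -- grid ------------------------------------------------------------------

def write_grid(path, grid: BinGrid, seed: int | None = None, **config) -> None:
    _write(path, provenance_header(seed, bin_size=grid.bin_size, **config),
           grid.to_dataframe(), with_columns=True)


def read_grid(path) -> BinGrid:
    df = pd.read_csv(path, sep="\t", comment="#")
    return BinGrid.from_dataframe(df)


# -- counts ----------------------------------------------------------------

def write_counts(path, counts: BinCounts, seed: int | None = None, **config) -> None:
    df = pd.DataFrame(
        {
            "chrom": counts.grid.chrom,
            "start": counts.grid.start,
            "end": counts.grid.end,
            "count": counts.counts,
        }
    )
    header = provenance_header(seed, sample_id=counts.sample_id, **config)
    _write(path, header, df, with_columns=True)


def read_counts(path, grid: BinGrid, sample_id: str | None = None) -> BinCounts:
    if sample_id is None:
        sample_id = _header_field(path, "sample_id") or "sample"
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) != grid.n_bins:
        raise FormatError(
            f"{path}: {len(df)} rows but grid has {grid.n_bins} bins"
        )
    if not (
        np.array_equal(df["start"].to_numpy(), grid.start)
        and list(df["chrom"]) == list(grid.chrom)
    ):
        raise FormatError(f"{path}: bin coordinates do not match grid")
    return BinCounts(grid, df["count"].to_numpy(dtype=np.int64), sample_id=sample_id)


def _header_field(path, key: str) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith(f"# {key}="):
                return line.split("=", 1)[1].strip()
    return None


# -- BED-family ------------------------------------------------------------

def write_truth_bed(path, truth: TruthProfile, seed: int | None = None) -> None:
    """Truth regions as BED5 with the integer copy number in the score column."""
    df = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "name": f"CN{cn}", "score": cn}
            for c, s, e, cn in truth.regions
        ]
    )
    _write(path, provenance_header(seed, purity=truth.purity), df, with_columns=False)


def read_truth_bed(path, purity: float = 1.0) -> TruthProfile:
    purity_hdr = _header_field(path, "purity")
    if purity_hdr is not None:
        purity = float(purity_hdr)
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "name", "score"],
    )
    regions = tuple(
        (r.chrom, int(r.start), int(r.end), int(r.score)) for r in df.itertuples()
    )
    return TruthProfile(regions, purity=purity)


def read_blacklist_bed(path) -> BlacklistRegions:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return BlacklistRegions.from_intervals(
        (r.chrom, int(r.start), int(r.end)) for r in df.itertuples()
    )


def write_blacklist_bed(path, blacklist: BlacklistRegions) -> None:
    df = pd.DataFrame(blacklist.regions, columns=["chrom", "start", "end"])
    _write(path, provenance_header(None), df, with_columns=False)


def write_calls_bed(path, profile: CNProfile, seed: int | None = None) -> None:
    """Called gain/loss segments as BED4 (name = gain|loss)."""
    rows = [
        {"chrom": s.chrom, "start": s.start, "end": s.end, "name": s.call}
        for s in profile.segments
        if s.call in ("gain", "loss")
    ]
    header = provenance_header(
        seed, sample_id=profile.sample_id,
        gain_thr=profile.gain_thr, loss_thr=profile.loss_thr,
    )
    _write(path, header, pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
           with_columns=False)


# -- SEG -------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "seg_mean"]


def write_seg(path, profile: CNProfile, seed: int | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": profile.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_bins": s.n_bins,
                "seg_mean": round(s.mean, 6),
            }
            for s in profile.segments
        ],
        columns=SEG_COLUMNS,
    )
    header = provenance_header(
        seed, sample_id=profile.sample_id,
        gain_thr=profile.gain_thr, loss_thr=profile.loss_thr,
    )
    _write(path, header, df, with_columns=True)


def read_seg(path, gain_thr: float | None = None, loss_thr: float | None = None) -> CNProfile:
    """Load a SEG file and re-derive calls from the recorded thresholds.

    Thresholds default to those in the file's provenance header, falling
    back to the package defaults.
    """
    if gain_thr is None:
        g = _header_field(path, "gain_thr")
        gain_thr = float(g) if g is not None else 0.15
    if loss_thr is None:
        l = _header_field(path, "loss_thr")
        loss_thr = float(l) if l is not None else -0.15
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing SEG columns {sorted(missing)}")
    sample = str(df["sample"].iloc[0]) if len(df) else "sample"
    segments = [
        Segment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_bins=int(r.n_bins), mean=float(r.seg_mean),
        )
        for r in df.itertuples()
    ]
    return call_segments(segments, gain_thr=gain_thr, loss_thr=loss_thr,
                         sample_id=sample)


# -- bedGraph --------------------------------------------------------------

def write_bedgraph(path, track: RatioTrack, seed: int | None = None) -> None:
    ok = np.isfinite(track.values)
    df = pd.DataFrame(
        {
            "chrom": track.grid.chrom[ok],
            "start": track.grid.start[ok],
            "end": track.grid.end[ok],
            "value": np.round(track.values[ok], 6),
        }
    )
    _write(path, provenance_header(seed, sample_id=track.sample_id), df,
           with_columns=False)


# -- misc ------------------------------------------------------------------

def write_tsv(path, df: pd.DataFrame, seed: int | None = None, **config) -> None:
    _write(path, provenance_header(seed, **config), df, with_columns=True)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_newick(path, newick: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick + "\n")
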