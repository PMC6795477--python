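"""Readers and writers for the small set of standard formats the package
speaks: tab-delimited probe tables (chrom, position, value), bedGraph and
fixed-step wiggle tracks, BED mask lists, and the reusable origin-list
file.

Internal coordinates are 1-based inclusive; BED/bedGraph files use their
native 0-based half-open convention, and the conversion happens here and
only here: the 1 kb bin covering bp 1..1000 is written as ``chrom 0 1000``.

Lines starting with ``#`` or ``track`` are treated as headers; writers
emit a provenance comment (package version and, when known, the seed).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedTrack, OriginSpec, ProbeTrack, RegionMask

logger = logging.getLogger(__name__)

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_bedgraph",
    "write_bedgraph",
    "write_wiggle",
    "read_bed_masks",
    "read_origin_list",
    "write_origin_list",
    "provenance_header",
]


def provenance_header(seed: int | None = None, config_text: str | None = None) -> str:
    from . import __version__

    parts = [f"orifire v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_text is not None:
        h = hashlib.sha256(config_text.encode()).hexdigest()[:12]
        parts.append(f"config_sha={h}")
    return "# " + " ".join(parts)


# ---------------------------------------------------------------------------
# probe tables


def read_probe_table(path: str | Path) -> dict[str, ProbeTrack]:
    """Read a tab-delimited (chrom, position, value) table into per-
    chromosome probe tracks.

    A header row is detected and skipped; rows are sorted by position and
    duplicate positions averaged with a warning.  Malformed rows raise
    with their line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3+ columns")
            try:
                rows.append((parts[0], int(float(parts[1])), float(parts[2])))
            except ValueError as exc:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=["chrom", "position", "value"])
    out = {}
    for chrom, g in df.groupby("chrom", sort=True):
        g = g.sort_values("position")
        dup = g["position"].duplicated().sum()
        if dup:
            logger.warning("%s: %d duplicate probe positions on %s averaged", path, dup, chrom)
            g = g.groupby("position", as_index=False)["value"].mean()
        out[str(chrom)] = ProbeTrack(
            str(chrom), g["position"].to_numpy(), g["value"].to_numpy()
        )
    return out


def write_probe_table(
    tracks: dict[str, ProbeTrack], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("#chrom\tposition\tvalue\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for p, v in zip(t.positions, t.values):
                fh.write(f"{chrom}\t{p}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# bedGraph / wiggle


def write_bedgraph(
    tracks: dict[str, BinnedTrack] | BinnedTrack,
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write grid tracks as bedGraph (0-based half-open); NaN bins are
    omitted and restored as missing on read."""
    if isinstance(tracks, BinnedTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for p, v in zip(t.positions, t.values):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{p - 1}\t{p - 1 + t.step}\t{v:.10g}\n")


def read_bedgraph(path: str | Path) -> dict[str, BinnedTrack]:
    """Read a uniform-step bedGraph back into grid tracks.

    All intervals on a chromosome must share one step and align to one
    grid; overlapping intervals are an error.  Gaps become NaN bins.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")[:4]
            per_chrom.setdefault(c, []).append((int(s), int(e), float(v)))
    out = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        steps = {e - s for s, e, _ in ivs}
        if len(steps) != 1:
            raise ValueError(f"{path}: non-uniform interval widths on {chrom}")
        step = steps.pop()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping intervals on {chrom}")
        start0 = ivs[0][0]
        n = (ivs[-1][0] - start0) // step + 1
        vals = np.full(n, np.nan)
        for s, e, v in ivs:
            if (s - start0) % step:
                raise ValueError(f"{path}: off-grid interval on {chrom}")
            vals[(s - start0) // step] = v
        out[chrom] = BinnedTrack(chrom, start0 + 1, step, vals)
    return out


def write_wiggle(
    tracks: dict[str, BinnedTrack], path: str | Path, header: str | None = None
) -> None:
    """Fixed-step wiggle output (1-based starts per the wiggle spec)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            fh.write(f"fixedStep chrom={chrom} start={t.start} step={t.step} span={t.step}\n")
            for v in t.values:
                fh.write("NA\n" if np.isnan(v) else f"{v:.10g}\n")


# ---------------------------------------------------------------------------
# BED masks and origin lists


def read_bed_masks(path: str | Path, label: str = "custom") -> list[RegionMask]:
    """Read a BED (0-based half-open) exclusion list into 1-based masks."""
    masks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else label
            masks.append(RegionMask(chrom, s + 1, e, label=name))
    return masks


def read_origin_list(path: str | Path) -> list[OriginSpec]:
    """Read the reusable origin list (chrom, position, id)."""
    origins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom, position[, id]")
            chrom, pos = parts[0], int(float(parts[1]))
            oid = parts[2] if len(parts) > 2 else f"{chrom}:{pos}"
            origins.append(OriginSpec(oid, chrom, pos, competence=1.0))
    return origins


def write_origin_list(
    origins: list[OriginSpec], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("#chrom\tposition\tid\n")
        for o in origins:
            fh.write(f"{o.chrom}\t{o.position}\t{o.id}\n")
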