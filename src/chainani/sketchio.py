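"""Versioned binary sketch files.

Layout (little-endian):

* magic ``b"CANI"``, format version (u16);
* JSON-encoded :class:`SketchParams` fields + fingerprint (u32 length
  prefix);
* genome id (u32 length prefix, utf-8);
* contig table: count (u32), then per contig a length-prefixed name and
  a u64 length;
* marker section: count (u64) + sorted u64 hash array;
* u64 offset of the seed section (written so a reader can stop after
  the markers — database search keeps only markers resident);
* seed section: hash count (u64); sorted u64 hash array; per-hash
  occurrence counts (u32); flattened occurrence arrays (contig u32,
  position u32, strand u8).

Writing is canonical (hashes and markers sorted), so write → read →
write is byte-identical.
"""

from __future__ import annotations

import json
import struct
from dataclasses import fields
from pathlib import Path

import numpy as np

from .params import SketchParams
from .sketch import GenomeSketch

__all__ = ["SketchFormatError", "read_markers", "read_sketch", "write_sketch", "SKETCH_SUFFIX"]

_MAGIC = b"CANI"
_VERSION = 1
SKETCH_SUFFIX = ".cani"


class SketchFormatError(ValueError):
    """Raised for unreadable or corrupted sketch files."""


def _params_payload(params: SketchParams) -> bytes:
    d = {f.name: getattr(params, f.name) for f in fields(params)}
    return json.dumps(d, sort_keys=True).encode()


def write_sketch(sketch: GenomeSketch, params: SketchParams, path: str | Path) -> None:
    if sketch.params_fingerprint != params.fingerprint():
        raise ValueError("sketch fingerprint does not match the supplied params")
    hashes = sorted(sketch.seeds)
    counts = np.array([len(sketch.seeds[h]) for h in hashes], dtype=np.uint32)
    occs = [occ for h in hashes for occ in sketch.seeds[h]]
    contigs = np.array([o[0] for o in occs], dtype=np.uint32)
    positions = np.array([o[1] for o in occs], dtype=np.uint32)
    strands = np.array([o[2] for o in occs], dtype=np.uint8)
    markers = np.array(sorted(sketch.markers), dtype=np.uint64)

    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<H", _VERSION))
        payload = _params_payload(params)
        fh.write(struct.pack("<I", len(payload)))
        fh.write(payload)
        gid = sketch.genome_id.encode()
        fh.write(struct.pack("<I", len(gid)))
        fh.write(gid)
        fh.write(struct.pack("<I", len(sketch.contig_names)))
        for name, length in zip(sketch.contig_names, sketch.contig_lengths):
            nb = name.encode()
            fh.write(struct.pack("<I", len(nb)))
            fh.write(nb)
            fh.write(struct.pack("<Q", length))
        fh.write(struct.pack("<Q", markers.size))
        fh.write(markers.tobytes())
        # patched below with the true seed-section offset
        offset_pos = fh.tell()
        fh.write(struct.pack("<Q", 0))
        seed_start = fh.tell()
        fh.write(struct.pack("<Q", len(hashes)))
        fh.write(np.array(hashes, dtype=np.uint64).tobytes())
        fh.write(counts.tobytes())
        fh.write(contigs.tobytes())
        fh.write(positions.tobytes())
        fh.write(strands.tobytes())
        fh.seek(offset_pos)
        fh.write(struct.pack("<Q", seed_start))


def _read_exact(fh, n: int, path) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise SketchFormatError(f"truncated sketch file: {path}")
    return data


def _read_header(fh, path):
    if _read_exact(fh, 4, path) != _MAGIC:
        raise SketchFormatError(f"not a sketch file (bad magic): {path}")
    (version,) = struct.unpack("<H", _read_exact(fh, 2, path))
    if version != _VERSION:
        raise SketchFormatError(f"unsupported sketch format version {version}: {path}")
    (plen,) = struct.unpack("<I", _read_exact(fh, 4, path))
    try:
        pdict = json.loads(_read_exact(fh, plen, path))
        params = SketchParams(**pdict)
    except (ValueError, TypeError) as exc:
        raise SketchFormatError(f"corrupt parameter block in {path}: {exc}") from exc
    (glen,) = struct.unpack("<I", _read_exact(fh, 4, path))
    genome_id = _read_exact(fh, glen, path).decode()
    (n_contigs,) = struct.unpack("<I", _read_exact(fh, 4, path))
    names, lengths = [], []
    for _ in range(n_contigs):
        (nlen,) = struct.unpack("<I", _read_exact(fh, 4, path))
        names.append(_read_exact(fh, nlen, path).decode())
        (clen,) = struct.unpack("<Q", _read_exact(fh, 8, path))
        lengths.append(clen)
    (n_markers,) = struct.unpack("<Q", _read_exact(fh, 8, path))
    markers = np.frombuffer(_read_exact(fh, 8 * n_markers, path), dtype=np.uint64)
    (seed_offset,) = struct.unpack("<Q", _read_exact(fh, 8, path))
    return params, genome_id, names, lengths, markers, seed_offset


def read_markers(path: str | Path) -> tuple[SketchParams, GenomeSketch]:
    """Read only the header and marker section of a sketch file.

    The returned sketch has an empty seed map; database search keeps
    these lightweight records resident and loads full sketches one
    candidate at a time via :func:`read_sketch`.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            params, gid, names, lengths, markers, _ = _read_header(fh, path)
    except OSError as exc:
        raise SketchFormatError(f"cannot read sketch file {path}: {exc}") from exc
    sk = GenomeSketch(
        genome_id=gid, contig_names=names, contig_lengths=lengths,
        seeds={}, markers={int(m) for m in markers},
        params_fingerprint=params.fingerprint(),
    )
    return params, sk


def read_sketch(path: str | Path) -> tuple[SketchParams, GenomeSketch]:
    """Read a full sketch file back into memory (bit-exact round trip)."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            params, gid, names, lengths, markers, seed_offset = _read_header(fh, path)
            fh.seek(seed_offset)
            (n_hashes,) = struct.unpack("<Q", _read_exact(fh, 8, path))
            hashes = np.frombuffer(_read_exact(fh, 8 * n_hashes, path), dtype=np.uint64)
            counts = np.frombuffer(_read_exact(fh, 4 * n_hashes, path), dtype=np.uint32)
            total = int(counts.sum())
            contigs = np.frombuffer(_read_exact(fh, 4 * total, path), dtype=np.uint32)
            positions = np.frombuffer(_read_exact(fh, 4 * total, path), dtype=np.uint32)
            strands = np.frombuffer(_read_exact(fh, total, path), dtype=np.uint8)
    except OSError as exc:
        raise SketchFormatError(f"cannot read sketch file {path}: {exc}") from exc

    seeds: dict[int, list[tuple[int, int, bool]]] = {}
    pos = 0
    for h, cnt in zip(hashes, counts):
        seeds[int(h)] = [
            (int(contigs[i]), int(positions[i]), bool(strands[i]))
            for i in range(pos, pos + int(cnt))
        ]
        pos += int(cnt)
    sk = GenomeSketch(
        genome_id=gid, contig_names=names, contig_lengths=lengths,
        seeds=seeds, markers={int(m) for m in markers},
        params_fingerprint=params.fingerprint(),
    )
    return params, sk
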