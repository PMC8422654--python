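"""TPS landmark file reading and writing.

Supports LM=, CURVES=/POINTS=, ID=, IMAGE= and SCALE= records.  SCALE is
honoured on read (all coordinates multiplied by it, converting pixels to
physical units).  Curves carry no names in the TPS format and are attached
by order; trailing landmarks beyond the shape configuration can be mapped
to named auxiliary points (e.g. the notochord tip) via ``aux_names``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .morphometry import LandmarkConfig

__all__ = ["read_tps", "write_tps"]


class TPSParseError(ValueError):
    pass


def _parse_coord(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TPSParseError(f"line {lineno}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TPSParseError(f"line {lineno}: non-numeric coordinate {line!r}") from exc


def read_tps(
    path,
    curve_names: Sequence[str] | None = None,
    aux_names: Sequence[str] = (),
) -> list[LandmarkConfig]:
    """Parse a TPS file into landmark configurations.

    ``curve_names`` assigns names to curves by order (generic names
    ``curve1`` ... otherwise); the last ``len(aux_names)`` landmarks of
    each record are detached from the shape and stored as named auxiliary
    points."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfig] = []
    i = 0
    n_lines = len(lines)

    def next_nonempty(j):
        while j < n_lines and not lines[j].strip():
            j += 1
        return j

    while True:
        i = next_nonempty(i)
        if i >= n_lines:
            break
        line = lines[i].strip()
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"line {i + 1}: expected LM= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"line {i + 1}: bad LM count in {line!r}") from exc
        i += 1
        coords = []
        for _ in range(k):
            i = next_nonempty(i)
            if i >= n_lines or "=" in lines[i]:
                raise TPSParseError(
                    f"line {min(i, n_lines - 1) + 1}: truncated record, "
                    f"expected {k} landmarks, got {len(coords)}"
                )
            coords.append(_parse_coord(lines[i].strip(), i + 1))
            i += 1
        coords = np.asarray(coords, float)

        curves: list[np.ndarray] = []
        specimen_id = None
        scale = None
        while True:
            i = next_nonempty(i)
            if i >= n_lines:
                break
            line = lines[i].strip()
            key = line.split("=", 1)[0].upper() if "=" in line else None
            if key == "LM":
                break
            if key == "CURVES":
                n_curves = int(line.split("=", 1)[1])
                i += 1
                for _ in range(n_curves):
                    i = next_nonempty(i)
                    if i >= n_lines or not lines[i].strip().upper().startswith("POINTS="):
                        raise TPSParseError(f"line {i + 1}: expected POINTS= record")
                    m = int(lines[i].strip().split("=", 1)[1])
                    i += 1
                    pts = []
                    for _ in range(m):
                        i = next_nonempty(i)
                        if i >= n_lines or "=" in lines[i]:
                            raise TPSParseError(
                                f"line {min(i, n_lines - 1) + 1}: truncated curve"
                            )
                        pts.append(_parse_coord(lines[i].strip(), i + 1))
                        i += 1
                    curves.append(np.asarray(pts, float))
            elif key == "ID":
                specimen_id = line.split("=", 1)[1].strip()
                i += 1
            elif key == "IMAGE":
                i += 1
            elif key == "SCALE":
                scale = float(line.split("=", 1)[1])
                i += 1
            else:
                raise TPSParseError(f"line {i + 1}: unexpected record {line!r}")

        if specimen_id is None:
            specimen_id = f"specimen{len(configs) + 1}"
        if scale is not None:
            coords = coords * scale
            curves = [c * scale for c in curves]

        n_aux = len(aux_names)
        aux = {}
        if n_aux:
            if coords.shape[0] <= n_aux:
                raise TPSParseError(
                    f"record {specimen_id!r}: {coords.shape[0]} landmarks cannot "
                    f"hold {n_aux} auxiliary points"
                )
            for name, pt in zip(aux_names, coords[-n_aux:]):
                aux[name] = pt
            coords = coords[:-n_aux]

        named = {}
        for j, c in enumerate(curves):
            if curve_names is not None and j < len(curve_names):
                named[curve_names[j]] = c
            else:
                named[f"curve{j + 1}"] = c

        # split "<id>_<stage>" identifiers written by this package
        stage = None
        if "_s" in specimen_id:
            base, _, tail = specimen_id.rpartition("_s")
            try:
                stage = float(tail)
                specimen_id = base
            except ValueError:
                stage = None
        configs.append(
            LandmarkConfig(
                specimen_id=specimen_id,
                stage=stage,
                coords=coords,
                curves=named,
                aux_points=aux,
                scale=scale,
            )
        )
    return configs


def write_tps(
    configs: Sequence[LandmarkConfig],
    path,
    aux_names: Sequence[str] = (),
    scale: float | None = None,
) -> None:
    """Write configurations to TPS.  Auxiliary points named in
    ``aux_names`` are appended as trailing landmarks; when ``scale`` is
    given, coordinates are divided by it and a SCALE= record written (so a
    round-trip through :func:`read_tps` restores the original units)."""
    inv = 1.0 / scale if scale else 1.0
    with open(path, "w") as fh:
        for cfg in configs:
            pts = [cfg.coords]
            for name in aux_names:
                if name not in cfg.aux_points:
                    raise KeyError(f"configuration {cfg.specimen_id!r} lacks aux point {name!r}")
                pts.append(cfg.aux_points[name][None, :])
            allpts = np.vstack(pts) * inv
            fh.write(f"LM={allpts.shape[0]}\n")
            for x, y in allpts:
                fh.write(f"{x:.10g} {y:.10g}\n")
            if cfg.curves:
                fh.write(f"CURVES={len(cfg.curves)}\n")
                for c in cfg.curves.values():
                    c = np.asarray(c, float) * inv
                    fh.write(f"POINTS={c.shape[0]}\n")
                    for x, y in c:
                        fh.write(f"{x:.10g} {y:.10g}\n")
            ident = cfg.specimen_id
            if cfg.stage is not None:
                ident = f"{ident}_s{cfg.stage:g}" if isinstance(cfg.stage, (int, float)) else f"{ident}_s{cfg.stage}"
            fh.write(f"ID={ident}\n")
            if scale:
                fh.write(f"SCALE={scale:.10g}\n")
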