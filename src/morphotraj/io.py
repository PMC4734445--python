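"""Readers and writers for 2D landmark data.

Landmark configurations travel in three containers:

* **TPS** — the plain-text records written by the tpsDig family of
  digitizing tools (``LM=``, coordinate lines, ``ID=``, ``IMAGE=``,
  ``SCALE=``).  The community standard for 2D landmark work.
* **CSV** — one specimen per row with a documented header
  ``specimen,taxon,stage,x1,y1,...,xk,yk``; round-trips bit-exactly for
  finite decimal input.
* **MorphoJ projects** — best-effort, see :func:`read_morphoj_project`.

All coordinates are planar with y pointing up (standard TPS orientation,
origin bottom left) and x along the anteroposterior axis.  Every specimen
in one data set must be digitized facing the same direction: the
downstream Procrustes fit forbids reflections and cannot rescue mirrored
specimens.
"""

from __future__ import annotations

import gzip
import logging
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("morphotraj")

STAGES = ("juvenile", "adult")


class MalformedInputError(ValueError):
    """Raised when a landmark or tree file violates its format contract."""


@dataclass
class LandmarkConfiguration:
    """One specimen's raw 2D landmark matrix.

    coords are in arbitrary digitizing units; ``scale`` (units per
    coordinate step, from a TPS ``SCALE=`` record) is carried along but
    *not* applied — the caller decides, because centroid sizes are only
    comparable across specimens under a uniform scaling policy.
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2)
    taxon: str = ""
    stage: Optional[str] = None  # "juvenile" | "adult" | None
    is_semilandmark: Optional[np.ndarray] = None  # (k,) bool
    scale: Optional[float] = None
    image: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise MalformedInputError(
                f"specimen {self.specimen_id!r}: coords must be k x 2, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = np.argwhere(~np.isfinite(self.coords))[0]
            raise MalformedInputError(
                f"specimen {self.specimen_id!r}: missing/non-finite coordinate at landmark "
                f"{bad[0] + 1}"
            )
        if self.stage is not None and self.stage not in STAGES:
            raise MalformedInputError(
                f"specimen {self.specimen_id!r}: stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.is_semilandmark is not None:
            self.is_semilandmark = np.asarray(self.is_semilandmark, dtype=bool)
            if self.is_semilandmark.shape != (self.k,):
                raise MalformedInputError(
                    f"specimen {self.specimen_id!r}: semilandmark mask length "
                    f"{self.is_semilandmark.shape} != k={self.k}"
                )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Coordinates as a 2k vector (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(-1)


def check_common_k(configs: Sequence[LandmarkConfiguration]) -> int:
    """Assert all configurations share one landmark count and return it."""
    if not configs:
        raise MalformedInputError("empty data set")
    k = configs[0].k
    for c in configs:
        if c.k != k:
            raise MalformedInputError(
                f"inconsistent landmark counts: specimen {c.specimen_id!r} has k={c.k}, "
                f"expected k={k}"
            )
    return k


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^(LM|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def read_tps(path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations, in file order.

    ``SCALE=`` values are captured but not applied to the coordinates.
    Raises :class:`MalformedInputError` naming the offending record when a
    specimen's coordinate count disagrees with its ``LM=`` header.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    lm_expected: Optional[int] = None
    coords: list[list[float]] = []
    meta: dict = {}
    n_records = 0

    def flush() -> None:
        nonlocal lm_expected, coords, meta
        if lm_expected is None:
            return
        if len(coords) != lm_expected:
            raise MalformedInputError(
                f"{path.name}: record {n_records} (id={meta.get('id', '?')!r}) declares "
                f"LM={lm_expected} but has {len(coords)} coordinate pairs"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta.get("id", f"specimen_{len(configs) + 1}"),
                coords=np.array(coords, dtype=float),
                scale=meta.get("scale"),
                image=meta.get("image"),
            )
        )
        lm_expected, coords, meta = None, [], {}

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _TPS_KEY.match(line)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key == "LM":
                flush()
                n_records += 1
                lm_expected = int(value)
            elif key == "ID":
                meta["id"] = value
            elif key == "IMAGE":
                meta["image"] = value
            elif key == "SCALE":
                meta["scale"] = float(value)
            continue
        if lm_expected is None:
            raise MalformedInputError(f"{path.name}: coordinate line before any LM= record")
        parts = line.split()
        if len(parts) != 2:
            raise MalformedInputError(
                f"{path.name}: record {n_records}: expected 'x y', got {line!r}"
            )
        coords.append([float(parts[0]), float(parts[1])])
    flush()
    if not configs:
        raise MalformedInputError(f"{path.name}: no TPS records found")
    check_common_k(configs)
    return configs


def write_tps(path, configs: Iterable[LandmarkConfiguration]) -> None:
    lines: list[str] = []
    for c in configs:
        lines.append(f"LM={c.k}")
        for x, y in c.coords:
            lines.append(f"{float(x)!r} {float(y)!r}")
        if c.image:
            lines.append(f"IMAGE={c.image}")
        lines.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            lines.append(f"SCALE={float(c.scale)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def read_landmark_csv(path, mask: Optional[Sequence[int] | np.ndarray] = None
                      ) -> list[LandmarkConfiguration]:
    """Read the documented CSV layout: specimen,taxon,stage,x1,y1,...,xk,yk.

    ``mask`` marks semilandmarks, either as a boolean vector of length k or
    as 1-based landmark indices.
    """
    df = pd.read_csv(path, dtype={"specimen": str, "taxon": str, "stage": str},
                     float_precision="round_trip")
    expected = ["specimen", "taxon", "stage"]
    if list(df.columns[:3]) != expected:
        raise MalformedInputError(
            f"{Path(path).name}: header must start with {expected}, got {list(df.columns[:3])}"
        )
    coord_cols = list(df.columns[3:])
    if len(coord_cols) % 2 != 0 or not coord_cols:
        raise MalformedInputError(f"{Path(path).name}: odd number of coordinate columns")
    k = len(coord_cols) // 2
    sl = _normalize_mask(mask, k)
    configs = []
    for _, row in df.iterrows():
        vals = row[coord_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            j = int(np.argwhere(~np.isfinite(vals))[0][0]) // 2 + 1
            raise MalformedInputError(
                f"{Path(path).name}: specimen {row['specimen']!r}: missing value at landmark {j}"
            )
        stage = row["stage"] if isinstance(row["stage"], str) and row["stage"] else None
        configs.append(
            LandmarkConfiguration(
                specimen_id=row["specimen"],
                taxon=row["taxon"] if isinstance(row["taxon"], str) else "",
                stage=stage,
                coords=vals.reshape(k, 2),
                is_semilandmark=sl,
            )
        )
    check_common_k(configs)
    return configs


def write_landmark_csv(path, configs: Sequence[LandmarkConfiguration]) -> None:
    k = check_common_k(configs)
    cols = ["specimen", "taxon", "stage"]
    for i in range(1, k + 1):
        cols += [f"x{i}", f"y{i}"]
    rows = []
    for c in configs:
        # repr round-trips doubles exactly, so read-after-write is bit-exact
        rows.append([c.specimen_id, c.taxon, c.stage or ""]
                    + [repr(float(v)) for v in c.flat()])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _normalize_mask(mask, k: int) -> Optional[np.ndarray]:
    if mask is None:
        return None
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (k,):
            raise MalformedInputError(f"semilandmark mask length {mask.shape} != k={k}")
        return mask.copy()
    out = np.zeros(k, dtype=bool)
    idx = mask.astype(int)
    if idx.min() < 1 or idx.max() > k:
        raise MalformedInputError("semilandmark indices must be 1-based and <= k")
    out[idx - 1] = True
    return out


def read_semilandmark_mask(path, k: int) -> np.ndarray:
    """Read a mask file: one 1-based semilandmark index per line."""
    idx = [int(s) for s in Path(path).read_text().split()]
    return _normalize_mask(np.array(idx), k)


# ---------------------------------------------------------------------------
# MorphoJ (best effort)
# ---------------------------------------------------------------------------


def read_morphoj_project(path):
    """Best-effort reader for MorphoJ project files (EXPERIMENTAL).

    The MorphoJ project container is not publicly specified; this reader is
    reverse-engineered against a small XML-flavoured subset (optionally
    gzip- or zip-compressed) carrying ``<dataset>`` elements whose
    ``<specimen>`` children hold whitespace-separated coordinates and
    optional ``taxon``/``stage`` classifier attributes.  Stored analyses
    are ignored.  Anything else raises with advice to export to TPS/CSV
    from MorphoJ itself, which is the supported escape hatch.

    Returns ``(configs, tree)``; ``tree`` is currently always ``None``
    (trees ride in separate NEXUS files in practice).
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    elif raw[:2] == b"PK":
        with zipfile.ZipFile(path) as zf:
            raw = zf.read(zf.namelist()[0])
    text = raw.decode("utf-8", errors="replace")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise MalformedInputError(
            f"{path.name}: unrecognized MorphoJ container ({exc}); export the data set from "
            "MorphoJ to TPS or CSV and use read_tps/read_landmark_csv instead"
        ) from exc
    configs: list[LandmarkConfiguration] = []
    missing_classifiers = False
    for ds in root.iter("dataset"):
        for sp in ds.iter("specimen"):
            vals = np.array([float(v) for v in (sp.text or "").split()])
            if vals.size % 2:
                raise MalformedInputError(
                    f"{path.name}: specimen {sp.get('id', '?')!r}: odd coordinate count"
                )
            stage = sp.get("stage")
            if stage is None:
                missing_classifiers = True
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sp.get("id", f"specimen_{len(configs) + 1}"),
                    taxon=sp.get("taxon", ""),
                    stage=stage,
                    coords=vals.reshape(-1, 2),
                )
            )
    if not configs:
        raise MalformedInputError(
            f"{path.name}: no datasets found; export to TPS/CSV from MorphoJ as a fallback"
        )
    if missing_classifiers:
        logger.warning("%s: project lacks stage classifiers; stage left unset", path.name)
    check_common_k(configs)
    return configs, None
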