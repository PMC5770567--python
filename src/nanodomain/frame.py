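"""Per-frame bilayer configurations and a flat CSV+JSON on-disk format.

A :class:`BilayerFrame` holds one time point of a two-leaflet lipid system:
in-plane reference-site coordinates per lipid, species labels, optional
heights and chain sites, inside a rectangular periodic box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Leaflet", "BilayerFrame", "write_frame", "read_frame",
           "write_trajectory", "read_trajectory_flat", "wrap"]


def wrap(xy: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Wrap in-plane coordinates into [0, Lx) x [0, Ly)."""
    box = np.asarray(box, dtype=float)
    return np.mod(np.asarray(xy, dtype=float), box)


@dataclass(eq=False)
class Leaflet:
    """One leaflet: per-lipid reference sites, species labels, optional extras.

    Parameters
    ----------
    xy : (n, 2) array
        In-plane positions in nm, wrapped into the box.
    species : (n,) array of str
        Species label per lipid (e.g. ``"sat"``, ``"unsat"``, ``"chol"``).
    z : (n,) array, optional
        Height per reference site in nm.
    chains : (n, n_chains, n_sites, 3) array, optional
        Ordered 3D chain-site coordinates per lipid, nm. Chain-order
        analysis needs at least 3 sites per chain.
    """

    xy: np.ndarray
    species: np.ndarray
    z: np.ndarray | None = None
    chains: np.ndarray | None = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.species = np.asarray(self.species)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.species) != len(self.xy):
            raise ValueError("species and xy length mismatch")

    @property
    def n(self) -> int:
        return len(self.xy)

    def species_names(self) -> list[str]:
        return sorted(np.unique(self.species).tolist())


@dataclass(eq=False)
class BilayerFrame:
    """One time point of a two-leaflet bilayer in a periodic box."""

    upper: Leaflet
    lower: Leaflet
    box: tuple[float, float]
    time: float = 0.0  # ns
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lx, ly = self.box
        if lx <= 0 or ly <= 0:
            raise ValueError("box lengths must be positive")
        for leaf in (self.upper, self.lower):
            xy = leaf.xy
            if np.any(xy < 0) or np.any(xy[:, 0] >= lx) or np.any(xy[:, 1] >= ly):
                leaf.xy = wrap(xy, self.box)

    @property
    def leaflets(self) -> dict[str, Leaflet]:
        return {"upper": self.upper, "lower": self.lower}

    def species_names(self) -> list[str]:
        names = set(self.upper.species_names()) | set(self.lower.species_names())
        return sorted(names)


def _leaflet_df(leaf: Leaflet) -> pd.DataFrame:
    z = leaf.z if leaf.z is not None else np.zeros(leaf.n)
    return pd.DataFrame({
        "id": np.arange(leaf.n),
        "species": leaf.species,
        "x": leaf.xy[:, 0],
        "y": leaf.xy[:, 1],
        "z": z,
    })


def write_frame(frame: BilayerFrame, prefix: str | Path) -> list[Path]:
    """Write one frame as ``<prefix>_upper.csv``, ``<prefix>_lower.csv`` and
    a ``<prefix>.json`` sidecar with box, time and any generator metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, leaf in frame.leaflets.items():
        p = prefix.with_name(prefix.name + f"_{name}.csv")
        _leaflet_df(leaf).to_csv(p, index=False, float_format="%.17g")
        paths.append(p)
    sidecar = prefix.with_suffix(".json")
    meta = {"box": list(frame.box), "time_ns": frame.time}
    meta.update({k: v for k, v in frame.meta.items()
                 if isinstance(v, (int, float, str, list, dict, bool, type(None)))})
    sidecar.write_text(json.dumps(meta, indent=1))
    paths.append(sidecar)
    return paths


def read_frame(prefix: str | Path) -> BilayerFrame:
    """Round-trip reader for :func:`write_frame` output."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    leaves = {}
    for name in ("upper", "lower"):
        df = pd.read_csv(prefix.with_name(prefix.name + f"_{name}.csv"),
                         float_precision="round_trip")
        leaves[name] = Leaflet(
            xy=df[["x", "y"]].to_numpy(),
            species=df["species"].to_numpy(dtype=str),
            z=df["z"].to_numpy(),
        )
    box = tuple(meta.pop("box"))
    time = meta.pop("time_ns", 0.0)
    return BilayerFrame(upper=leaves["upper"], lower=leaves["lower"],
                        box=box, time=time, meta=meta)


def write_trajectory(frames: Sequence[BilayerFrame], outdir: str | Path,
                     stem: str = "frame") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, fr in enumerate(frames):
        written += write_frame(fr, outdir / f"{stem}_{i:05d}")
    return written


def read_trajectory_flat(indir: str | Path, stem: str = "frame") -> list[BilayerFrame]:
    indir = Path(indir)
    sidecars = sorted(indir.glob(f"{stem}_*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no '{stem}_*.json' frames under {indir}")
    return [read_frame(p.with_suffix("")) for p in sidecars]
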