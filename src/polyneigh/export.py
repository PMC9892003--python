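"""Export helpers: CCP4/MRC volumes, voxel tables, mask serialization, plots."""

from __future__ import annotations

import json

import gemmi
import numpy as np
import pandas as pd

from .neighborhood_map import HistogramGeometry, ProbabilityHistogram
from .polysome_linker import DirectionMask

__all__ = [
    "volume_to_ccp4",
    "histogram_to_csv",
    "projection_to_csv",
    "mask_to_json",
    "mask_from_json",
    "plot_association",
]


def volume_to_ccp4(volume: np.ndarray, voxel_size: float, path) -> None:
    """Write a 3D grid as a CCP4/MRC map with the voxel size in the header."""
    vol = np.ascontiguousarray(np.asarray(volume, dtype=np.float32))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(vol)
    n = vol.shape
    m.grid.unit_cell = gemmi.UnitCell(
        n[0] * voxel_size, n[1] * voxel_size, n[2] * voxel_size, 90, 90, 90
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def histogram_to_csv(hist: ProbabilityHistogram, path) -> None:
    hist.to_voxel_frame().to_csv(path, index=False)


def projection_to_csv(projection: np.ndarray, geometry: HistogramGeometry, path) -> None:
    c = geometry.voxel_centers()
    df = pd.DataFrame(projection, index=c, columns=c)
    df.index.name = "x_angstrom"
    df.to_csv(path)


def mask_to_json(mask: DirectionMask, path) -> None:
    """Serialize a direction mask as JSON (geometry + true-voxel indices)."""
    payload = {
        "direction": mask.direction,
        "provenance": mask.provenance,
        "voxel_size": mask.geometry.voxel_size,
        "half_extent_voxels": mask.geometry.half_extent_voxels,
        "voxels": np.argwhere(mask.voxels).tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def mask_from_json(path) -> DirectionMask:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    geometry = HistogramGeometry(
        voxel_size=payload["voxel_size"],
        half_extent_voxels=payload["half_extent_voxels"],
    )
    voxels = np.zeros(geometry.shape, dtype=bool)
    idx = np.asarray(payload["voxels"], dtype=int)
    if idx.size:
        voxels[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return DirectionMask(
        geometry=geometry,
        voxels=voxels,
        direction=payload["direction"],
        provenance=payload.get("provenance", ""),
    )


def plot_association(
    predicted: pd.DataFrame,
    per_tomogram: pd.DataFrame,
    outcome: str,
    path,
    abundance: float | None = None,
    title: str = "",
) -> None:
    """Dot-and-error-bar plot of modelled probabilities per state.

    Black circles are the modelled means with CI whiskers; small scattered
    points are the per-tomogram event frequencies; an optional horizontal
    line marks the random-association probability.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = predicted[predicted["outcome"] == outcome]
    states = list(sel["state"])
    xs = np.arange(len(states))
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(states), 3.4))
    rng = np.random.default_rng(0)  # fixed scatter jitter for reproducible output
    for x, s in zip(xs, states):
        freqs = per_tomogram.loc[per_tomogram["group"] == s, "frequency"]
        if len(freqs):
            ax.scatter(
                x + rng.uniform(-0.18, 0.18, len(freqs)), freqs,
                s=5, color="tab:blue", alpha=0.35, linewidths=0, zorder=1,
            )
    ax.errorbar(
        xs, sel["probability"],
        yerr=[sel["probability"] - sel["ci_low"], sel["ci_high"] - sel["probability"]],
        fmt="o", color="black", capsize=3, zorder=3,
    )
    if abundance is not None:
        ax.axhline(abundance, color="red", lw=1, label="random association")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(xs, states, rotation=45, ha="right")
    ax.set_ylabel(f"P({outcome})")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "polyneigh"})
    plt.close(fig)
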