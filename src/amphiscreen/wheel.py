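"""Helical-wheel layouts: residue angles and physicochemical classes.

Looking down the helix axis, consecutive residues advance 100°, so 18
residues (five turns) complete a full 20-position cycle and residue n shares
its angle with residue n+18. The layout pairs each residue with its angle
and a physicochemical class used for colouring (hydrophobic vs cationic
faces are what the screen selects for).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .peptide_io import PeptideRecord

#: Residue class table following the usual wheel-colouring convention.
#: Glycine is classed polar (small, no side-chain face preference).
DEFAULT_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIMFWYC"},
    **{aa: "cationic" for aa in "KRH"},
    **{aa: "anionic" for aa in "DE"},
    **{aa: "polar" for aa in "GSTNQP"},
}


@dataclass
class WheelEntry:
    index: int        # 1-based residue position
    angle_deg: float  # [0, 360)
    residue: str
    klass: str


@dataclass
class WheelLayout:
    entries: list[WheelEntry]
    delta_deg: float = 100.0


def wheel_layout(
    record: Union[str, PeptideRecord],
    delta_deg: float = 100.0,
    classes: Mapping[str, str] = DEFAULT_CLASSES,
) -> WheelLayout:
    """One entry per residue: angle ``((n-1)*delta) mod 360`` and class."""
    seq = record.sequence if isinstance(record, PeptideRecord) else record.upper()
    entries = [
        WheelEntry(index=n, angle_deg=((n - 1) * delta_deg) % 360.0,
                   residue=aa, klass=classes[aa])
        for n, aa in enumerate(seq, start=1)
    ]
    return WheelLayout(entries=entries, delta_deg=delta_deg)


def helical_turns(length: int) -> float:
    """Number of α-helical turns for a given residue count (3.6 res/turn)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return length / 3.6


def layout_table(layout: WheelLayout, path: str | Path | None = None) -> pd.DataFrame:
    """Layout as a DataFrame (index, residue, angle, class); optional TSV."""
    df = pd.DataFrame(
        [
            {"index": e.index, "residue": e.residue,
             "angle_deg": e.angle_deg, "class": e.klass}
            for e in layout.entries
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


_CLASS_COLORS = {
    "hydrophobic": "#c0392b", "cationic": "#1a3a8f",
    "anionic": "#c97b1c", "polar": "#7f8c8d",
}


def plot_wheel(layout: WheelLayout, path: str | Path, title: str = "") -> None:
    """Render the wheel as an image (requires matplotlib).

    Residues spiral slightly outward with position so repeated angles stay
    visible; hydrophobic residues are red, cationic dark blue.
    """
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    n_total = len(layout.entries)
    for e in layout.entries:
        r = 1.0 + 0.35 * (e.index - 1) / max(n_total - 1, 1)
        theta = math.radians(90.0 - e.angle_deg)  # residue 1 at the top, clockwise
        x, y = r * math.cos(theta), r * math.sin(theta)
        ax.scatter([x], [y], s=550, color=_CLASS_COLORS[e.klass], zorder=3)
        ax.annotate(f"{e.residue}{e.index}", (x, y), ha="center", va="center",
                    color="white", fontsize=8, zorder=4)
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


__all__ = [
    "DEFAULT_CLASSES", "WheelEntry", "WheelLayout", "wheel_layout",
    "helical_turns", "layout_table", "plot_wheel",
]
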