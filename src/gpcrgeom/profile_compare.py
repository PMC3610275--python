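"""Ensemble-averaged helix profiles and profile differencing.

Per-frame profiles are averaged circularly (vector mean of angles), which is
exact for dihedrals straddling the +/-180 wrap where a naive arithmetic mean
fails.  Deltas are elementwise circular differences against a reference
profile, defined exactly where both inputs are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from ._geom import circular_mean, circular_sd, wrap_angle
from .helix_geometry import HelixProfile, helix_profile
from .structure_io import Ensemble

__all__ = [
    "EnsembleProfile",
    "ProfileDelta",
    "ensemble_profile",
    "profile_delta",
    "flag_distortion",
    "plot_delta",
]

CHANNELS = HelixProfile.CHANNELS


@dataclass
class EnsembleProfile:
    profile_mean: HelixProfile
    profile_sd: HelixProfile
    n_frames: int
    peptide_label: str = ""

    @property
    def positions(self) -> List[int]:
        return self.profile_mean.positions


@dataclass
class ProfileDelta:
    positions: List[int]
    delta_phi: Dict[int, float] = field(default_factory=dict)
    delta_psi: Dict[int, float] = field(default_factory=dict)
    delta_bend: Dict[int, float] = field(default_factory=dict)
    delta_twist: Dict[int, float] = field(default_factory=dict)

    _BY_CHANNEL = {
        "phi": "delta_phi",
        "psi": "delta_psi",
        "unit_bend": "delta_bend",
        "unit_twist": "delta_twist",
    }

    def channel(self, name: str) -> Dict[int, float]:
        return getattr(self, self._BY_CHANNEL[name])

    def to_tsv(self) -> str:
        lines = ["position\tdelta_phi\tdelta_psi\tdelta_bend\tdelta_twist"]
        for p in self.positions:
            vals = [self.channel(c).get(p, math.nan) for c in CHANNELS]
            lines.append(
                "\t".join(
                    [str(p)]
                    + [f"{v:.3f}" if math.isfinite(v) else "NA" for v in vals]
                )
            )
        return "\n".join(lines) + "\n"


def ensemble_profile(
    ensemble: Ensemble,
    chain: str,
    motif_res_seq: int,
    offsets: Sequence[int] = tuple(range(-7, 5)),
    peptide_label: str = "",
) -> EnsembleProfile:
    """Circular mean/sd of per-frame helix profiles over an ensemble."""
    frames = [
        helix_profile(model, chain, motif_res_seq, offsets) for model in ensemble
    ]
    mean = HelixProfile(positions=list(offsets))
    sd = HelixProfile(positions=list(offsets))
    for channel in CHANNELS:
        for off in offsets:
            values = [f.channel(channel).get(off, math.nan) for f in frames]
            arr = np.asarray(values, float)
            if np.all(np.isnan(arr)):
                continue
            mean.channel(channel)[off] = circular_mean(arr)
            sd.channel(channel)[off] = circular_sd(arr)
    return EnsembleProfile(
        profile_mean=mean,
        profile_sd=sd,
        n_frames=len(ensemble),
        peptide_label=peptide_label,
    )


def profile_delta(test: EnsembleProfile, reference: EnsembleProfile) -> ProfileDelta:
    """Elementwise circular difference (test - reference) in (-180, 180]."""
    common = [p for p in test.positions if p in reference.positions]
    if not common:
        raise ValueError("profiles share no positions")
    delta = ProfileDelta(positions=common)
    for channel in CHANNELS:
        t = test.profile_mean.channel(channel)
        r = reference.profile_mean.channel(channel)
        for p in common:
            tv, rv = t.get(p, math.nan), r.get(p, math.nan)
            if math.isfinite(tv) and math.isfinite(rv):
                delta.channel(channel)[p] = wrap_angle(tv - rv)
    return delta


def flag_distortion(delta: ProfileDelta, threshold: float) -> dict:
    """Per-channel flags where |delta| exceeds the threshold.

    Returns {"flags": {channel: [positions]}, "unperturbed": bool}; the
    summary verdict is "unperturbed" iff no channel is flagged anywhere.
    """
    flags: Dict[str, List[int]] = {}
    for channel in CHANNELS:
        hits = [
            p
            for p, v in sorted(delta.channel(channel).items())
            if math.isfinite(v) and abs(v) > threshold
        ]
        if hits:
            flags[channel] = hits
    return {"flags": flags, "unperturbed": not flags}


def plot_delta(deltas: Dict[str, ProfileDelta], path: Optional[str] = None):
    """Four-panel delta plot (phi, psi, bend, twist vs position offset)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    titles = {
        "phi": r"$\Delta\Phi$",
        "psi": r"$\Delta\Psi$",
        "unit_bend": r"$\Delta$ unit bend",
        "unit_twist": r"$\Delta$ unit twist",
    }
    for ax, channel in zip(axes.flat, CHANNELS):
        for label, delta in deltas.items():
            xs = delta.positions
            ys = [delta.channel(channel).get(p, math.nan) for p in xs]
            ax.plot(xs, ys, marker="o", ms=3, label=label)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(titles[channel])
        ax.set_xlabel("position relative to motif residue i")
        ax.set_ylabel("degrees")
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
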