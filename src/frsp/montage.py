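"""Electrode montage: 64-channel 10-10 layout and the six analysis clusters.

The statistical analysis operates on six clusters of five electrodes each,
uniformly distributed over the two hemispheres (frontal, central and
parieto-occipital, left and right). All other channels are carried through
the simulation but receive no injected effect and enter no statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The six analysis clusters. Keys are ``<region>_<hemisphere>``.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "frontal_left": ("F1", "F3", "FC1", "FC3", "FC5"),
    "frontal_right": ("F2", "F4", "FC2", "FC4", "FC6"),
    "central_left": ("C1", "C3", "C5", "CP1", "CP3"),
    "central_right": ("C2", "C4", "C6", "CP2", "CP4"),
    "parieto_occipital_left": ("P5", "PO3", "P7", "PO7", "O1"),
    "parieto_occipital_right": ("P6", "PO4", "P8", "PO8", "O2"),
}

_CLUSTER_CHANNELS: tuple[str, ...] = tuple(
    ch for chans in CLUSTERS.values() for ch in chans
)

#: Filler channels bringing the montage to 64 (10-10 labels, outside clusters).
_FILLERS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "Fz", "F6", "F8",
    "FT7", "FCz", "FT8",
    "T7", "Cz", "T8",
    "TP7", "CPz", "TP8",
    "P1", "P3", "Pz", "P2", "P4", "P9", "P10",
    "POz", "Oz", "Iz", "TP9", "TP10",
)

DEFAULT_CHANNELS: tuple[str, ...] = _CLUSTER_CHANNELS + _FILLERS


def hemisphere_of(cluster: str) -> str:
    """'left' or 'right' half of a cluster name."""
    return cluster.rsplit("_", 1)[1]


def region_of(cluster: str) -> str:
    """Region (frontal / central / parieto_occipital) of a cluster name."""
    return cluster.rsplit("_", 1)[0]


def is_posterior(label: str) -> bool:
    """Posterior scalp sites (parietal/occipital), used for the idle alpha rhythm."""
    return label[0] in ("P", "O", "I")


@dataclass(frozen=True)
class MontageSpec:
    """Channel labels plus the cluster map used throughout the pipeline."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    clusters: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CLUSTERS)
    )

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels in montage")
        seen: set[str] = set()
        for name, chans in self.clusters.items():
            if seen & set(chans):
                raise ValueError(f"cluster {name!r} overlaps another cluster")
            seen.update(chans)
            missing = set(chans) - set(self.channels)
            if missing:
                raise ValueError(f"cluster {name!r} references unknown channels {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        return self.channels.index(label)

    def cluster_indices(self, cluster: str) -> list[int]:
        return [self.channels.index(ch) for ch in self.clusters[cluster]]

    def analysis_channels(self) -> list[str]:
        """All channels belonging to some cluster, in cluster order."""
        return [ch for chans in self.clusters.values() for ch in chans]


DEFAULT_MONTAGE = MontageSpec()
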