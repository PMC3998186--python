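"""Synthetic band matrices and densitometry tables.

RAPD band presence/absence is simulated as independent binary characters
evolving on a known tree: a band exists at the root with probability ``p0``;
along a branch of length t a present band is lost with probability
``1 - exp(-mu * t)`` (a mutation at the primer site abolishes amplification),
and an absent band is gained with small per-branch probability ``g``
(homoplasy — two unrelated samples showing a comigrating product).  Gel
scoring noise is modelled by observing each truly present band in each of
``r`` replicate amplifications with probability ``q``; the analysed matrix
keeps bands seen in at least 2 replicates, the same reproducibility rule the
scoring applies to real gels.

Densitometry tables are simulated from a known linear calibration: each
standard level and each sample is measured ``n`` times, with Gaussian noise
on the peak areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chemotax.band_matrix import BandMatrix, filter_reproducible

__all__ = [
    "SimTree",
    "TreeSpec",
    "BandSimConfig",
    "DensSimConfig",
    "simulate_band_matrix",
    "simulate_densitometry",
]

# nested-pair topology: a leaf name, or a tuple of (child, branch_length) pairs
TreeSpec = str | tuple


@dataclass(frozen=True)
class SimTree:
    """A rooted tree with branch lengths, the truth behind a simulated matrix.

    ``topology`` is nested pairs: a leaf is its name (str); an internal node
    is a tuple of ``(child, branch_length)`` pairs, e.g. a balanced quartet::

        SimTree(((("A", 0.1), ("B", 0.1)), 0.4),
                ((("C", 0.1), ("D", 0.1)), 0.4))

    is written ``SimTree(topology=((inner_AB, 0.4), (inner_CD, 0.4)))``.
    """

    topology: tuple

    def __post_init__(self) -> None:
        names = self.leaf_names
        if len(names) < 2:
            raise ValueError("tree needs at least 2 leaves")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        self._check(self.topology)

    @staticmethod
    def _check(node: TreeSpec) -> None:
        if isinstance(node, str):
            return
        for child, length in node:
            if length < 0:
                raise ValueError("negative branch length")
            SimTree._check(child)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        out: list[str] = []

        def walk(node: TreeSpec) -> None:
            if isinstance(node, str):
                out.append(node)
            else:
                for child, _ in node:
                    walk(child)

        walk(self.topology)
        return tuple(out)

    @classmethod
    def from_newick(cls, text: str) -> "SimTree":
        """Build from a Newick string (branch lengths required, default 0)."""
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")

        def convert(node) -> tuple[TreeSpec, float]:
            length = node.edge.length or 0.0
            if node.is_leaf():
                return node.taxon.label.replace(" ", "_"), length
            return tuple(convert(c) for c in node.child_nodes()), length

        spec, _ = convert(tree.seed_node)
        return cls(spec)

    @classmethod
    def balanced_quartet(
        cls, tip_length: float = 0.1, internal_length: float = 0.4
    ) -> "SimTree":
        """((A,B),(C,D)) with short tip branches and long internal branches."""
        ab = ((("A", tip_length), ("B", tip_length)), internal_length)
        cd = ((("C", tip_length), ("D", tip_length)), internal_length)
        return cls((ab, cd))


@dataclass(frozen=True)
class BandSimConfig:
    """Parameters of the band-evolution and gel-scoring model.

    Defaults mirror a 30-primer RAPD screen of roughly 10 scorable bands per
    primer; the loss rate mu is per unit branch length, the gain probability
    g is per branch, and q is the per-replicate detection probability of a
    truly present band.
    """

    n_primers: int = 30
    bands_per_primer: int = 10
    p0: float = 0.6
    mu: float = 0.5
    g: float = 0.01
    r: int = 3
    q: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primers < 1 or self.bands_per_primer < 1 or self.r < 1:
            raise ValueError("counts must be >= 1")
        for name in ("p0", "g", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class DensSimConfig:
    """Parameters of the densitometry generator.

    ``true_concentrations`` maps sample names to true concentrations in table
    units; the default calibration (slope/intercept) and standard levels match
    a four-level verbascoside standard series, and ``area_noise_sd`` is in
    densitometer area units.  Every standard level and every sample is
    measured ``n`` times.
    """

    true_concentrations: dict[str, float] = field(
        default_factory=lambda: {"S1": 4.0, "S2": 7.5, "S3": 11.0}
    )
    slope: float = 2.2846e-05
    intercept: float = -1.9405
    area_noise_sd: float = 2000.0
    n: int = 5
    standard_concentrations: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0)
    rf: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.area_noise_sd < 0:
            raise ValueError("area noise SD must be >= 0")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if any(c <= 0 for c in self.true_concentrations.values()):
            raise ValueError("true concentrations must be positive")


def _evolve_band(
    node: TreeSpec, state: np.ndarray, cfg: BandSimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Propagate the vector of band states down one subtree."""
    if isinstance(node, str):
        return {node: state}
    out: dict[str, np.ndarray] = {}
    for child, length in node:
        p_loss = 1.0 - np.exp(-cfg.mu * length)
        u = rng.random(state.shape)
        child_state = np.where(
            state == 1, (u >= p_loss).astype(np.uint8), (u < cfg.g).astype(np.uint8)
        )
        out.update(_evolve_band(child, child_state, cfg, rng))
    return out


def simulate_band_matrix(
    tree: SimTree, cfg: BandSimConfig, filter_min_count: int = 2
) -> tuple[BandMatrix, list[BandMatrix]]:
    """Simulate replicate RAPD gels on ``tree`` and the filtered matrix.

    Returns ``(filtered, replicates)``: the reproducibility-filtered matrix
    (band kept per sample when seen in >= ``filter_min_count`` of the ``r``
    replicates) and the raw per-replicate observation matrices.  Deterministic
    for a fixed ``cfg.seed``.
    """
    if cfg.r < filter_min_count:
        raise ValueError(
            f"r={cfg.r} replicates cannot support min_count={filter_min_count} filtering"
        )
    rng = np.random.default_rng(cfg.seed)
    samples = tree.leaf_names
    n_bands = cfg.n_primers * cfg.bands_per_primer
    bands = tuple(
        (f"P{i + 1:02d}", 100 * (j + 1))
        for i in range(cfg.n_primers)
        for j in range(cfg.bands_per_primer)
    )
    root_state = (rng.random(n_bands) < cfg.p0).astype(np.uint8)
    leaf_states = _evolve_band(tree.topology, root_state, cfg, rng)
    truth = np.stack([leaf_states[s] for s in samples])
    replicates = []
    for _ in range(cfg.r):
        detected = (rng.random(truth.shape) < cfg.q).astype(np.uint8)
        replicates.append(BandMatrix(samples, bands, truth * detected))
    filtered = filter_reproducible(replicates, min_count=filter_min_count)
    return filtered, replicates


def simulate_densitometry(cfg: DensSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a standards table and replicate sample tracks.

    Areas are generated by inverting the calibration,
    ``area = (conc - intercept) / slope``, plus Gaussian noise of SD
    ``cfg.area_noise_sd``; every standard level and every sample receives
    ``cfg.n`` replicate measurements.  Deterministic for a fixed seed.

    Returns ``(standards, tracks)`` in the CSV dialects of
    :mod:`chemotax.densitometry`.
    """
    rng = np.random.default_rng(cfg.seed)

    def areas_for(conc: float, n: int) -> np.ndarray:
        center = (conc - cfg.intercept) / cfg.slope
        return center + rng.normal(0.0, cfg.area_noise_sd, size=n)

    std_rows = []
    for level, conc in enumerate(cfg.standard_concentrations, start=1):
        for area in areas_for(conc, cfg.n):
            std_rows.append((level, conc, area))
    standards = pd.DataFrame(std_rows, columns=["level", "concentration", "area"])

    track_rows = []
    for sample, conc in cfg.true_concentrations.items():
        for rep, area in enumerate(areas_for(conc, cfg.n), start=1):
            track_rows.append((sample, rep, area, cfg.rf))
    tracks = pd.DataFrame(track_rows, columns=["sample", "replicate", "area", "rf"])
    return standards, tracks
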