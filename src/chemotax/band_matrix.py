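"""Binary RAPD band matrices: container, TSV format, filtering and summaries.

A RAPD profile scores each sample for the presence (1) or absence (0) of an
amplification product, identified by the primer that produced it and its
approximate size in base pairs.  Band identity across samples is by
``(primer, size)`` exactly as gels are scored; no tolerance matching of sizes
is attempted — scored matrices are the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "read_band_matrix",
    "write_band_matrix",
    "filter_reproducible",
    "polymorphism_summary",
    "unique_band_counts",
]

BandId = tuple[str, int]


@dataclass(frozen=True)
class BandMatrix:
    """Samples x bands presence/absence matrix, bands grouped by primer.

    Parameters
    ----------
    samples
        Unique sample identifiers, one per row.
    bands
        ``(primer, approximate size in bp)`` pairs, one per column; unique
        within each primer.
    presence
        Binary matrix of shape ``(len(samples), len(bands))``.
    """

    samples: tuple[str, ...]
    bands: tuple[BandId, ...]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        samples = tuple(str(s) for s in self.samples)
        bands = tuple((str(p), int(s)) for p, s in self.bands)
        presence = np.asarray(self.presence)
        if presence.ndim != 2 or presence.shape != (len(samples), len(bands)):
            raise ValueError(
                f"presence shape {presence.shape} does not match "
                f"{len(samples)} samples x {len(bands)} bands"
            )
        if len(samples) < 2:
            raise ValueError("a band matrix needs at least 2 samples")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample id")
        if len(set(bands)) != len(bands):
            raise ValueError("duplicate (primer, size) band id")
        if presence.size and not np.isin(presence, (0, 1)).all():
            raise ValueError("band states must be 0 or 1")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "presence", presence.astype(np.uint8))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def primers(self) -> tuple[str, ...]:
        """Primer ids in first-appearance order."""
        seen: dict[str, None] = {}
        for primer, _ in self.bands:
            seen.setdefault(primer)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p}|{s}" for p, s in self.bands]
        return pd.DataFrame(self.presence, index=list(self.samples), columns=cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.bands == other.bands
            and np.array_equal(self.presence, other.presence)
        )


def _parse_band_id(token: str) -> BandId:
    primer, sep, size = token.partition("|")
    if not sep or not primer:
        raise ValueError(f"malformed band id {token!r}; expected 'primer|size_bp'")
    try:
        return primer, int(size)
    except ValueError:
        raise ValueError(f"malformed band size in {token!r}") from None


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band matrix from TSV.

    Format: header line ``sample<TAB>primer|size ...``; one row per sample
    with 0/1 cells.  Malformed cells are rejected with the offending row and
    column named.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no samples")
    header = lines[0].split("\t")
    if header[0] != "sample":
        raise ValueError(f"{path}: header must start with 'sample'")
    bands = tuple(_parse_band_id(tok) for tok in header[1:])
    if len(lines) < 2:
        raise ValueError(f"{path}: no samples")
    samples: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(bands) + 1:
            raise ValueError(
                f"{path}: ragged row for sample {cells[0]!r} "
                f"({len(cells) - 1} cells, expected {len(bands)})"
            )
        sample, values = cells[0], cells[1:]
        if sample in samples:
            raise ValueError(f"{path}: duplicate sample id {sample!r}")
        row = []
        for band_tok, cell in zip(header[1:], values):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at sample {sample!r}, "
                    f"band {band_tok!r}"
                )
            row.append(int(cell))
        samples.append(sample)
        rows.append(row)
    return BandMatrix(tuple(samples), bands, np.array(rows, dtype=np.uint8))


def write_band_matrix(m: BandMatrix, path: str | Path) -> None:
    """Write ``m`` as tab-separated UTF-8 text (newline-terminated)."""
    path = Path(path)
    header = "sample\t" + "\t".join(f"{p}|{s}" for p, s in m.bands)
    lines = [header]
    for sample, row in zip(m.samples, m.presence):
        lines.append(sample + "\t" + "\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def filter_reproducible(
    replicates: Sequence[BandMatrix], min_count: int = 2
) -> BandMatrix:
    """Keep a band for a sample only if seen in at least ``min_count`` replicates.

    Mirrors the gel-scoring convention that only reproducible bands (observed
    at least twice across replicate amplifications) enter the analysis.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if len(replicates) < min_count:
        raise ValueError(
            f"need at least min_count={min_count} replicate matrices, "
            f"got {len(replicates)}"
        )
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.samples != first.samples or rep.bands != first.bands:
            raise ValueError("replicate matrices have mismatched sample/band sets")
    counts = np.sum([rep.presence for rep in replicates], axis=0)
    return BandMatrix(first.samples, first.bands, (counts >= min_count).astype(np.uint8))


def polymorphism_summary(m: BandMatrix) -> pd.DataFrame:
    """Per-primer band totals and polymorphism percentages.

    A column counts toward a primer's total when the band was amplified in at
    least one sample; it is polymorphic when present in some but not all
    samples.  A primer with no amplified bands reports total 0 and a missing
    percentage.

    Returns a frame indexed by primer with columns ``total_bands``,
    ``polymorphic_bands``, ``polymorphism_pct``.
    """
    if m.n_bands == 0:
        raise ValueError("band matrix has no band columns")
    colsum = m.presence.sum(axis=0)
    amplified = colsum > 0
    polymorphic = amplified & (colsum < m.n_samples)
    records = []
    primer_of = np.array([p for p, _ in m.bands])
    for primer in m.primers:
        mask = primer_of == primer
        total = int(amplified[mask].sum())
        poly = int(polymorphic[mask].sum())
        pct = 100.0 * poly / total if total else np.nan
        records.append((primer, total, poly, pct))
    return pd.DataFrame(
        records, columns=["primer", "total_bands", "polymorphic_bands", "polymorphism_pct"]
    ).set_index("primer")


def unique_band_counts(m: BandMatrix) -> pd.DataFrame:
    """Count bands present in exactly one sample, per (sample, primer).

    Returns a samples x primers frame of counts; each singleton column
    contributes 1 to the sample that carries it.
    """
    if m.n_bands == 0:
        raise ValueError("band matrix has no band columns")
    counts = pd.DataFrame(
        0, index=list(m.samples), columns=list(m.primers), dtype=int
    )
    colsum = m.presence.sum(axis=0)
    for j, (primer, _) in enumerate(m.bands):
        if colsum[j] == 1:
            i = int(np.flatnonzero(m.presence[:, j])[0])
            counts.loc[m.samples[i], primer] += 1
    return counts
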