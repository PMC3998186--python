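"""Per-primer polymorphism percentages and unique-band counts.

Reads results/bands.tsv (from 01_simulate_bands.py) and writes the two
marker-level summary tables a RAPD study reports: total and polymorphic
bands per primer, and the number of bands private to a single sample.
"""

from pathlib import Path

from chemotax.band_matrix import polymorphism_summary, read_band_matrix, unique_band_counts

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    m = read_band_matrix(OUT / "bands.tsv")
    summary = polymorphism_summary(m)
    summary.to_csv(OUT / "polymorphism.tsv", sep="\t")
    uniques = unique_band_counts(m)
    uniques.to_csv(OUT / "unique_bands.tsv", sep="\t")
    total = int(summary["total_bands"].sum())
    poly = int(summary["polymorphic_bands"].sum())
    print(f"{total} amplified bands across {len(summary)} primers; "
          f"{poly} polymorphic ({100 * poly / total:.1f}%)")
    print(f"unique bands per sample:\n{uniques.sum(axis=1).to_string()}")


if __name__ == "__main__":
    main()
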