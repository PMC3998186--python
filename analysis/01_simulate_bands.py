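"""Simulate the RAPD screen: replicate gels on a synthetic 15-sample tree.

The study's gel photographs were never published, so the band data here are
generated by the package's band-evolution model on a hand-written SYNTHETIC
tree (data/synthetic_study_tree.nwk) whose leaf names and qualitative
grouping mirror the sampled Phlomis accessions — it is a stand-in, not the
real genealogy.  30 primers x 10 candidate bands, three replicate gels,
bands kept when seen at least twice.

Writes results/bands.tsv (filtered) and the raw replicate matrices.
"""

from pathlib import Path

from chemotax.band_matrix import write_band_matrix
from chemotax.synthetic_data import BandSimConfig, SimTree, simulate_band_matrix

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    tree = SimTree.from_newick((ROOT / "data" / "synthetic_study_tree.nwk").read_text())
    cfg = BandSimConfig(n_primers=30, bands_per_primer=10, seed=seed)
    filtered, replicates = simulate_band_matrix(tree, cfg, filter_min_count=2)
    write_band_matrix(filtered, OUT / "bands.tsv")
    for k, rep in enumerate(replicates, start=1):
        write_band_matrix(rep, OUT / f"bands_replicate{k}.tsv")
    amplified = (filtered.presence.sum(axis=0) > 0).sum()
    print(
        f"simulated {filtered.n_samples} samples x {filtered.n_bands} candidate bands "
        f"({amplified} amplified in >=1 sample) with seed {seed}"
    )
    print(f"wrote {OUT / 'bands.tsv'} and {len(replicates)} replicate matrices")


if __name__ == "__main__":
    main()
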