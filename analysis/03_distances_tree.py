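"""Genetic distances and the UPGMA dendrogram from the band matrix.

Computes the simple-matching similarity matrix, converts to genetic
distances d = 1 - Ssm, reports the closest and farthest pairs, builds the
UPGMA tree and writes it as Newick.
"""

import itertools
from pathlib import Path

from chemotax.band_matrix import read_band_matrix
from chemotax.distance_clustering import (
    genetic_distance_matrix,
    simple_matching_matrix,
    to_newick,
    upgma,
    write_phylip_distances,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    m = read_band_matrix(OUT / "bands.tsv")
    ssm = simple_matching_matrix(m)
    d = genetic_distance_matrix(ssm)
    write_phylip_distances(d, OUT / "distances.phylip")
    pairs = [
        (d.values[i, j], d.ids[i], d.ids[j])
        for i, j in itertools.combinations(range(d.n), 2)
    ]
    lo, hi = min(pairs), max(pairs)
    print(f"closest pair:  {lo[1]} vs {lo[2]} (d = {lo[0]:.3f})")
    print(f"farthest pair: {hi[1]} vs {hi[2]} (d = {hi[0]:.3f})")
    t = upgma(d)
    (OUT / "upgma.nwk").write_text(to_newick(t, precision=6) + "\n")
    print(f"UPGMA root height {t.height:.3f}; tree written to {OUT / 'upgma.nwk'}")


if __name__ == "__main__":
    main()
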