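"""Mantel test: do genetic distances track verbascoside-level differences?

Joins the genetic distance matrix from 03_distances_tree.py (simulated
genotypes on the synthetic stand-in tree) with the real quantification table
from 04_quantify_verbascoside.py on the nine chemotyped samples, and runs a
one-sided Mantel permutation test for positive association.  Because the
genotypes are synthetic, the resulting r and p illustrate the statistic
rather than re-test the study's claim.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chemotax.concordance import concentration_difference_matrix, mantel
from chemotax.distance_clustering import DistanceMatrix, read_phylip_distances

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main(seed: int = 0) -> None:
    d = read_phylip_distances(OUT / "distances.phylip")
    quant = pd.read_csv(OUT / "quantification.tsv", sep="\t").set_index("sample")
    quant = quant.rename(columns={"concentration_mean": "mean_concentration"})
    shared = [s for s in d.ids if s in quant.index]
    idx = [d.ids.index(s) for s in shared]
    d_shared = DistanceMatrix(tuple(shared), d.values[np.ix_(idx, idx)])
    conc_d = concentration_difference_matrix(quant.loc[shared])
    result = mantel(d_shared, conc_d, n_perm=9999, seed=seed)
    (OUT / "concordance.json").write_text(result.to_json_line() + "\n")
    print(f"{len(shared)} samples shared between genetic and chemical data")
    print(
        f"Mantel r = {result.r:.3f}, one-sided p = {result.p:.4f} "
        f"({result.n_perm} permutations, seed {seed})"
    )


if __name__ == "__main__":
    main()
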