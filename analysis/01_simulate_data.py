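"""Generate the reference synthetic dataset used by the downstream steps.

44 taxa (the sample size of the motivating cross-country study), a
strongly phylogenetic trait (lambda = 0.9, phi = 0) on a Yule tree, a
25-tree synthetic "posterior" made by perturbing branch lengths, and
uniform coordinates in a Eurasia-sized box.  Writes trees (Newick),
coordinates + trait (CSV) and the generating-truth manifest (YAML) to
results/synthetic/.
"""

import pathlib

import pandas as pd
import yaml

from psgls import make_dataset

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20180411
N_TIPS, LAM, PHI, SIGMA2, N_TREES = 44, 0.9, 0.0, 1.0, 25


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(n_tips=N_TIPS, lam=LAM, phi=PHI, sigma2=SIGMA2,
                      seed=SEED, n_trees=N_TREES)
    (OUT / "trees.nwk").write_text(
        "\n".join(t.as_newick() for t in ds.trees) + "\n"
    )
    pd.DataFrame({
        "taxon": ds.taxa,
        "lat": ds.points.lat,
        "lon": ds.points.lon,
        "trait": ds.y,
    }).to_csv(OUT / "data.csv", index=False)
    (OUT / "truth.yaml").write_text(yaml.safe_dump({
        "n_tips": N_TIPS, "lambda": LAM, "phi": PHI, "sigma2": SIGMA2,
        "n_trees": N_TREES, "seed": SEED,
    }, sort_keys=False))
    print(f"wrote {N_TREES} trees, coordinates and trait for {N_TIPS} taxa "
          f"(true lambda={LAM}, phi={PHI}) to {OUT}")


if __name__ == "__main__":
    main()
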