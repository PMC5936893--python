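"""Can the grid search tell ancestry from proximity? Desk-scale check.

Simulates traits at a small grid of true (lambda, phi) pairs — purely
phylogenetic, purely spatial, mixed, and null — and reports how well the
exhaustive grid search recovers them and how often the likelihood-ratio
tests fire.  25 replicates per truth keeps this a quick desk run; the
acceptance script repeats the headline pairs at 200 replicates.
"""

import pathlib

from psgls import identifiability_experiment

ROOT = pathlib.Path(__file__).resolve().parent.parent
TRUTHS = [(0.9, 0.0), (0.0, 0.9), (0.5, 0.4), (0.0, 0.0)]


def main() -> None:
    tbl = identifiability_experiment(TRUTHS, reps=25, n_tips=44, seed=7)
    out = ROOT / "results" / "identifiability.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    tbl.to_csv(out, sep="\t", index=False, float_format="%.4g")
    print(tbl.to_string(index=False))
    pure = tbl.set_index(["lam_true", "phi_true"])
    print(
        f"\npurely phylogenetic traits recover mean lambda-hat = "
        f"{pure.loc[(0.9, 0.0), 'mean_lam_hat']:.2f}; purely spatial traits "
        f"recover mean phi-hat = {pure.loc[(0.0, 0.9), 'mean_phi_hat']:.2f}; "
        f"the null rejects the ancestry test in "
        f"{pure.loc[(0.0, 0.0), 'reject_lambda']:.0%} of replicates."
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
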