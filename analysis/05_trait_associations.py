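"""Relate species trend coefficients to life-history traits.

On a synthetic species set (trait table and birth-death phylogeny labeled
by the simulated species), fits one univariate OLS per trait (adjusted
R^2) and the matching phylogenetic GLS with maximum-likelihood Pagel's
lambda, both for all species and with migratory species excluded.  The
response is the per-species trend coefficient from script 04 when
available, otherwise a Brownian-plus-trait simulated response so the
script stands alone.

Usage: python analysis/05_trait_associations.py [--out results] [--seed 1]
"""

import argparse
import pathlib
import random
import warnings

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from lepitrend import traits as tr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-species", type=int, default=60)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    trends_path = args.out / "species_trends.csv"
    coefs = None
    if trends_path.exists():
        table = pd.read_csv(trends_path).set_index("species_id")
        if len(table) >= 30:  # enough species for stable trait regressions
            coefs = table["trend_coef"]
            print(f"using {len(coefs)} species trend coefficients from {trends_path}")
        else:
            print(f"{trends_path} has only {len(table)} species; "
                  "using stand-alone simulated trends instead")

    # synthetic phylogeny + traits for a species set large enough for PGLS
    n = args.n_species if coefs is None else len(coefs)
    species = [f"sp{i + 1:03d}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(species)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa, rng=random.Random(args.seed),
    )
    trait_table = tr.simulate_trait_table(species, rng)
    labels, V = tr.brownian_vcv(tree, taxa=species)

    if coefs is None:
        # stand-alone mode: simulate trends with real trait signal + phylogeny
        uni = (trait_table["voltinism"] == "univoltine").astype(float)
        coefs = pd.Series(
            -0.02 - 0.03 * uni.to_numpy()
            + 0.02 * tr.simulate_brownian(V / np.diag(V).mean(), rng),
            index=species,
        )
        print(f"simulated {n} species trend coefficients "
              "(univoltine species decline faster; Brownian residuals)")

    rows = []
    for trait in tr.TRAIT_COLUMNS:
        for excl in (False, True):
            try:
                ols = tr.fit_trait_ols(coefs, trait_table, trait,
                                       exclude_migratory=excl)
            except ValueError as err:
                print(f"  {trait} (excl_migratory={excl}): skipped ({err})")
                continue
            design = tr.trait_design(
                trait_table if not excl else trait_table[~trait_table["migratory"]],
                trait,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pgls = tr.fit_pgls(coefs, design, tree)
            for level in ols["params"].index[1:]:
                rows.append({
                    "trait": trait,
                    "level": level,
                    "exclude_migratory": excl,
                    "ols_coef": ols["params"][level],
                    "ols_p": ols["pvalues"][level],
                    "ols_adj_r2": ols["adj_r2"],
                    "pgls_coef": pgls.params[level],
                    "pgls_se": pgls.se[level],
                    "pgls_p": pgls.pvalues[level],
                    "pgls_lambda": pgls.lambda_,
                })
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "trait_associations.csv", index=False)
    shown = out[~out["exclude_migratory"]]
    print(f"trait models fitted for {shown['trait'].nunique()} traits "
          f"({len(shown)} levels); wrote trait_associations.csv")
    top = shown.sort_values("ols_adj_r2", ascending=False).head(3)
    for _, r in top.iterrows():
        print(f"  {r['trait']}/{r['level']}: OLS coef {r['ols_coef']:+.3f} "
              f"(adj R2 {r['ols_adj_r2']:.2f}), PGLS coef {r['pgls_coef']:+.3f} "
              f"(lambda {r['pgls_lambda']:.2f}, p {r['pgls_p']:.2g})")


if __name__ == "__main__":
    main()
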