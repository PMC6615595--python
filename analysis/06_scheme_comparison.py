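"""Standardize trends across monitoring schemes.

Converts published cumulative total-abundance changes of the long-running
European butterfly monitoring schemes to annualized geometric-mean rates,
verifies internal consistency of each published row, and appends the
synthetic scheme's estimate from script 04 when available.

Usage: python analysis/06_scheme_comparison.py [--out results]
"""

import argparse
import json
import pathlib

from lepitrend import compare


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()

    schemes = list(compare.EUROPEAN_SCHEMES)
    manifest = args.out / "manifest_04.json"
    if manifest.exists():
        with open(manifest) as fh:
            m = json.load(fh)
        rate = m["annual_rate_percent"]
        cum = compare.annual_to_cumulative(rate, 20)
        schemes.append(compare.SchemeSummary(
            "synthetic scheme (this analysis)", 20, 50, cum, rate,
        ))
        print(f"appended synthetic scheme: {rate:.1f}%/yr ({cum:.0f}% over 20 y)")

    table = compare.build_comparison_table(schemes)
    table.to_csv(args.out / "scheme_comparison.csv", index=False)
    display = table.rename(columns={
        "cumulative_percent": "cumulative",
        "annual_percent_printed": "printed",
        "annual_percent_recomputed": "recomputed",
    })
    display["cumulative"] = display["cumulative"].round(1)
    display["printed"] = display["printed"].round(1)
    display["recomputed"] = display["recomputed"].round(1)
    print(display[["region", "cumulative", "printed", "recomputed"]]
          .to_string(index=False))
    n_bad = int(table["inconsistent"].sum())
    print(f"{'no' if n_bad == 0 else n_bad} internal inconsistencies "
          "between printed cumulative and annual rates")


if __name__ == "__main__":
    main()
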