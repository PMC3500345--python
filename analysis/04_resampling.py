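"""Distribution-free check of the sweep: empirical resampling p-values.

For each gene-set size n the gene set is redrawn 1000 times uniformly from
the reference and the original overlap with the QTL test set is compared with
the resampled overlaps (p_emp = fraction of resamples with at least the
original overlap). Agreement with the analytic hypergeometric tail confirms
the parametric model.
"""

from pathlib import Path

import pandas as pd

from heteronet import io
from heteronet.enrichment import empirical_pvalue
from heteronet.ora import expected_overlap, hypergeom_pvalue

DATA = Path("results/data")
SCORING = Path("results/scoring")
OUT = Path("results/ora")
SEED = 211


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = io.read_catalog(DATA / "catalog.tsv")
    reference = sorted(catalog.gene_ids)
    test_set = set(io.read_gene_list(DATA / "qtl_test_set.txt"))
    ranked = io.read_gene_list(SCORING / "ranking_mph_H12.txt")

    a, t = len(reference), len(test_set)
    rows = []
    for i, n in enumerate(range(100, min(801, len(ranked) + 1), 100)):
        res = empirical_pvalue(reference, test_set, ranked, n=n, B=1000,
                               seed=SEED + i)
        analytic = (hypergeom_pvalue(a, t, n, res.k_orig)
                    if res.k_orig > expected_overlap(a, t, n) else None)
        rows.append({"n": n, "k_orig": res.k_orig, "B": res.B,
                     "count_ge": res.count_ge, "p_emp": res.p_emp,
                     "p_analytic": analytic})
        shown = "NA" if analytic is None else f"{analytic:.4f}"
        print(f"n={n:4d}: overlap {res.k_orig:3d}, empirical p={res.p_emp:.4f}, "
              f"analytic p={shown}")
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "resampling_mph_H12.tsv", sep="\t", index=False, na_rep="NA")
    print(f"-> {OUT}/resampling_mph_H12.tsv")


if __name__ == "__main__":
    main()
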