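"""Genomic relative-frequency profile of the top-ranked genes.

Bins each chromosome along the Kosambi-cM axis and plots, per bin, the
fraction of catalog genes that belong to the top-300 MPH ranking (normalizing
for local gene density), with the QTL regions shaded and the per-chromosome
median as a horizontal line.
"""

from pathlib import Path

from heteronet import io
from heteronet.profiles import plot_profile, relative_frequency_profile

DATA = Path("results/data")
SCORING = Path("results/scoring")
OUT = Path("results/profile")
TOP_N = 300


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = io.read_catalog(DATA / "catalog.tsv")
    qtl = io.read_qtl_regions(DATA / "qtl_regions.tsv", catalog)
    ranked = io.read_gene_list(SCORING / "ranking_mph_H12.txt")
    top = set(ranked[:TOP_N])

    prof = relative_frequency_profile(top, catalog, bin_width_cM=2.0, qtl=qtl)
    prof.table.to_csv(OUT / "frequency_profile.tsv", sep="\t", index=False,
                      na_rep="NA")
    plot_profile(prof, str(OUT / "frequency_profile.png"))

    for c, median in sorted(prof.medians.items()):
        sub = prof.table[(prof.table["chromosome"] == c)
                         & prof.table["rel_freq"].notna()]
        in_qtl = []
        for _, b in sub.iterrows():
            mid = (b["bin_start"] + b["bin_end"]) / 2
            if any(r["chromosome"] == c and r["cM_start"] <= mid < r["cM_end"]
                   for _, r in qtl.regions.iterrows()):
                in_qtl.append(b["rel_freq"])
        mean_qtl = sum(in_qtl) / len(in_qtl) if in_qtl else float("nan")
        print(f"chromosome {c}: median relative frequency {median:.3f}; "
              f"mean inside QTL regions {mean_qtl:.3f} ({len(in_qtl)} bins)")
    print(f"-> {OUT}/frequency_profile.tsv and .png")


if __name__ == "__main__":
    main()
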