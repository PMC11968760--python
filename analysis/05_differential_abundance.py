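"""Per-taxon two-group Wilcoxon tests at species and genus rank, plus the
Spearman co-occurrence matrix of the most abundant taxa."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    from twobrad.markers import MarkerDatabase
    from twobrad.stats import differential_abundance, spearman_matrix
    from twobrad.tables import AbundanceMatrix

    matrix = AbundanceMatrix.from_tsv(RESULTS / "03_abundance.tsv",
                                      RESULTS / "03_metadata.tsv")
    db = MarkerDatabase.load(SCRATCH / "db")

    res = differential_abundance(matrix)
    res.insert(1, "rank", "species")
    res.to_csv(RESULTS / "05_differential_species.tsv", sep="\t", index=False)
    sig = res[res["significant"]]
    print(f"species rank: {len(sig)} of {len(res)} taxa at p < 0.05")
    print(sig[["taxon", "mean_M", "mean_H", "p", "q", "direction"]]
          .round(4).to_string(index=False))

    # genus-level roll-up via the database lineages
    genus_cols = {}
    for sp in matrix.taxon_ids:
        genus_cols.setdefault(db.lineages[sp]["genus"], []).append(sp)
    gvals = pd.DataFrame({g: matrix.values[cols].sum(axis=1)
                          for g, cols in genus_cols.items()})
    gmat = AbundanceMatrix(values=gvals, groups=matrix.groups)
    gres = differential_abundance(gmat)
    gres.insert(1, "rank", "genus")
    gres.to_csv(RESULTS / "05_differential_genus.tsv", sep="\t", index=False)
    print(f"genus rank: {int(gres['significant'].sum())} of {len(gres)} "
          f"taxa at p < 0.05")

    rho, pmat = spearman_matrix(matrix, top_k=12)
    rho.round(4).to_csv(RESULTS / "05_spearman_rho.tsv", sep="\t")
    pmat.to_csv(RESULTS / "05_spearman_p.tsv", sep="\t")
    print(f"Spearman matrix over top {len(rho)} species written")


if __name__ == "__main__":
    main()
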