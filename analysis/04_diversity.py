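"""Alpha and beta diversity of the two groups.

Chao1/Shannon/Simpson per sample (on assigned read counts), two-group rank
tests on each index, the three beta-diversity distance matrices, PCoA
coordinates, and the presence/absence Venn partition.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    from twobrad.diversity import (alpha_diversity_frame, distance, pcoa,
                                   write_distance_tsv, write_pcoa_tsv)
    from twobrad.stats import wilcoxon_two_group
    from twobrad.tables import AbundanceMatrix

    matrix = AbundanceMatrix.from_tsv(RESULTS / "03_abundance.tsv",
                                      RESULTS / "03_metadata.tsv")
    counts = pd.read_csv(RESULTS / "03_counts.tsv", sep="\t", index_col="sample")

    alpha = alpha_diversity_frame(counts)
    alpha["group"] = matrix.groups
    alpha.to_csv(RESULTS / "04_alpha_diversity.tsv", sep="\t")
    print("alpha diversity (group means):")
    print(alpha.groupby("group").mean().round(3).to_string())
    for index in ("chao1", "shannon", "simpson"):
        x = alpha.loc[alpha["group"] == "M", index]
        y = alpha.loc[alpha["group"] == "H", index]
        _, p = wilcoxon_two_group(x, y)
        print(f"  {index}: M vs H Wilcoxon p = {p:.3f}")

    for metric in ("jaccard_binary", "bray_curtis", "euclidean"):
        dm = distance(matrix.values, metric)
        write_distance_tsv(dm, RESULTS / f"04_distance.{metric}.tsv")
        res = pcoa(dm, n_axes=3)
        write_pcoa_tsv(res, matrix.groups, RESULTS / f"04_pcoa.{metric}.tsv")
        exp = ", ".join(f"{f:.1%}" for f in res.explained_fraction[:2])
        print(f"  PCoA on {metric}: first two axes explain {exp}")

    venn = matrix.presence_partition()
    pd.Series(venn).to_csv(RESULTS / "04_venn.tsv", sep="\t", header=False)
    print(f"species detected: {venn}")


if __name__ == "__main__":
    main()
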