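"""LEfSe-style effect sizing of the two groups.

Kruskal-Wallis screen at alpha = 0.05 followed by bootstrapped LDA effect
sizes on the per-million scale; features with LDA score >= 2.0 are the
reported discriminants.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    from twobrad.stats import lefse
    from twobrad.tables import AbundanceMatrix

    matrix = AbundanceMatrix.from_tsv(RESULTS / "03_abundance.tsv",
                                      RESULTS / "03_metadata.tsv")
    res = lefse(matrix, alpha=0.05, lda_threshold=2.0, n_boot=30, seed=0)
    res.to_csv(RESULTS / "06_lefse.tsv", sep="\t", index=False)
    print(f"{len(res)} discriminative features at LDA score >= 2.0:")
    if not res.empty:
        print(res.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
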