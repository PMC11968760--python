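"""Profile every sample's reads against the marker database.

Runs the QC funnel (raw -> enzyme -> clean reads), exact marker matching,
G-score filtering (threshold 5, sqrt form) and coverage-normalised relative
abundance.  Writes the merged abundance matrix and QC table to results/ and
reports how well the profiles recover the simulated ground truth.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    from click.testing import CliRunner
    from twobrad.cli import main as cli

    fastqs = sorted((SCRATCH / "sim" / "reads").glob("*.fastq"))
    runner = CliRunner()
    res = runner.invoke(cli, ["profile", *map(str, fastqs),
                              "--db", str(SCRATCH / "db"),
                              "--metadata", str(SCRATCH / "sim" / "metadata.tsv"),
                              "--out", str(SCRATCH / "profiles")],
                        catch_exceptions=False)
    print(res.output, end="")

    for name, out in [("abundance.species.tsv", "03_abundance.tsv"),
                      ("qc.tsv", "03_qc_funnel.tsv"),
                      ("metadata.tsv", "03_metadata.tsv"),
                      ("counts.tsv", "03_counts.tsv")]:
        df = pd.read_csv(SCRATCH / "profiles" / name, sep="\t")
        df.to_csv(RESULTS / out, sep="\t", index=False)

    est = pd.read_csv(RESULTS / "03_abundance.tsv", sep="\t", index_col="sample")
    truth = pd.read_csv(SCRATCH / "sim" / "ground_truth.tsv", sep="\t",
                        index_col="sample")
    common = est.columns.intersection(truth.columns)
    err = (est[common] - truth[common]).abs()
    print(f"recovery vs ground truth over {len(common)} species: "
          f"max |error| = {err.values.max():.4f}, "
          f"mean |error| = {err.values.mean():.4f}")


if __name__ == "__main__":
    main()
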