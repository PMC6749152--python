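#!/usr/bin/env python
"""Hypergeometric over-representation analysis of the risk-crosstalk mRNAs
against the gene-set collection (BH FDR<0.05), then assemble the run
manifest. Writes results/run/enrichment/ and results/run/manifest.json."""

import argparse
from pathlib import Path

import pandas as pd

from circenet.io import read_id_list
from circenet.pipeline import PipelineConfig, stage_enrich, write_manifest


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    cfg = PipelineConfig.load(args.run_dir / "config.yaml")
    stage_enrich(cfg, args.run_dir)
    hits = sorted(read_id_list(args.run_dir / "enrichment" / "significant_terms.txt"))
    ora = pd.read_csv(args.run_dir / "enrichment" / "ora.tsv", sep="\t", index_col=0)
    print(f"terms enriched at FDR<{cfg.ora_fdr}: {hits}")
    print("top 3 terms:")
    print(ora.head(3)[["k", "K", "n", "N", "p", "fdr"]].to_string())
    manifest = write_manifest(cfg, args.run_dir)
    print(f"manifest written; top circRNA: {manifest['summary'].get('top_circ')}")


if __name__ == "__main__":
    main()
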