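#!/usr/bin/env python
"""Per-dataset empirical-Bayes moderated t, Stouffer meta-combination
across datasets (CDEGs at FDR<0.01) and single-dataset miRNA DE (DEmiRs
at FDR<0.05). Writes results/run/de/."""

import argparse
from pathlib import Path

from circenet.io import read_id_list
from circenet.pipeline import PipelineConfig, stage_de


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    cfg = PipelineConfig.load(args.run_dir / "config.yaml")
    stage_de(cfg, args.run_dir)
    cdegs = read_id_list(args.run_dir / "de" / "cdegs.txt")
    demirs = read_id_list(args.run_dir / "de" / "demirs.txt")
    print(f"CDEGs at FDR<{cfg.gene_fdr}: {len(cdegs)}")
    print(f"DEmiRs at FDR<{cfg.mir_fdr}: {len(demirs)}")


if __name__ == "__main__":
    main()
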