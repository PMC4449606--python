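"""Generate the synthetic study pangenome and write its data directory.

Two phylotype-like groups of three strains each, 200 single-copy core
families plus 150 gained/lost accessory families, planted recombination
tracts, CRISPR arrays with within-group protospacers, and Man-family PTS
operons. Everything downstream reads results/data/.
"""

from pathlib import Path

from beepan.pipeline import run_pipeline
from beepan.sim import PangenomeSimConfig

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    cfg = PangenomeSimConfig(seed=seed)
    results = run_pipeline(cfg, OUT, stages={"simulate"})
    print(f"simulated {results['n_genomes']} genomes, {results['n_genes']} genes")
    print(f"data written under {OUT / 'data'}")


if __name__ == "__main__":
    main()
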