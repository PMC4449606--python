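"""Descriptive genome statistics, tree-ordered synteny comparison pairs and
the synteny filter, on the simulated strains."""

from pathlib import Path

import pandas as pd

from beepan.io_formats import read_newick_file
from beepan.sim import PangenomeSimConfig, simulate_pangenome
from beepan.synteny import (
    SyntenyFilter,
    genome_summary,
    order_pairs_by_tree,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    sim = simulate_pangenome(PangenomeSimConfig(seed=seed))
    rows = [genome_summary(g, sim.annotations) for g in sim.genomes]
    stats = pd.DataFrame(rows)
    stats.to_csv(OUT / "genome_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))

    tree_path = OUT / "core_tree.nwk"
    if tree_path.exists():
        tree = read_newick_file(tree_path)
        tree.is_rooted = True
        pairs = order_pairs_by_tree([g.genome_id for g in sim.genomes], tree)
        print("adjacent comparison pairs along the core tree:", pairs)
    filt = SyntenyFilter()
    print(
        f"synteny filter: identity >= {filt.min_identity}%, "
        f"length >= {filt.min_length} bp (Firm-4 dialect: 50 bp)"
    )


if __name__ == "__main__":
    main()
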