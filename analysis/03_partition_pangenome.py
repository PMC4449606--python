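"""Partition the inferred families into pan-orthologs, group core, group
accessory and group-specific core, and count Venn regions per group."""

from pathlib import Path

import pandas as pd

from beepan import pangenome as pan
from beepan.io_formats import read_clusters
from beepan.sim import PangenomeSimConfig, simulate_pangenome

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    sim = simulate_pangenome(PangenomeSimConfig(seed=seed))
    clusters = read_clusters(OUT / "groups.txt")
    genomes = set(sim.truth.group_of_genome)
    groups = {
        gid: {g for g, grp in sim.truth.group_of_genome.items() if grp == gid}
        for gid in sorted({*sim.truth.group_of_genome.values()})
    }
    pan_orth = pan.extract_pan_orthologs(clusters, genomes)
    print(f"{len(pan_orth)} pan-orthologs (single copy in all {len(genomes)} genomes)")
    rows, venn_rows = [], []
    for gid, members in groups.items():
        core = pan.group_core(clusters, members)
        acc = pan.group_accessory(clusters, members)
        spec = pan.group_specific_core(clusters, members, genomes - members)
        print(
            f"group {gid}: {len(core)} core, {len(acc)} accessory, "
            f"{len(spec)} group-specific core families"
        )
        rows += [{"group": gid, "family": f, "label": "group-core"} for f in core]
        rows += [{"group": gid, "family": f, "label": "group-accessory"} for f in acc]
        for region, n in sorted(
            pan.venn_partition(clusters, acc, members).items(),
            key=lambda kv: sorted(kv[0]),
        ):
            venn_rows.append(
                {"group": gid, "region": "+".join(sorted(region)), "families": n}
            )
    pd.DataFrame(rows).to_csv(OUT / "partition.tsv", sep="\t", index=False)
    pd.DataFrame(venn_rows).to_csv(OUT / "venn.tsv", sep="\t", index=False)
    print(f"tables written to {OUT / 'partition.tsv'} and {OUT / 'venn.tsv'}")


if __name__ == "__main__":
    main()
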