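#!/usr/bin/env python
"""Complete-linkage clustering of the salinity-response profiles.

Builds the genes x roots matrix of log2(salt/control) ratios over the union
of DTGs (missing where a gene had no expression in a sample) and clusters it
with Euclidean distance and complete linkage.
"""

from pathlib import Path

import pandas as pd

from rootdge.clustering import ProfileMatrix, cluster_profiles, write_dendrogram

OUT = Path("results/analysis")


def main() -> None:
    calls = {root: pd.read_csv(OUT / f"dge_{root}.tsv", sep="\t") for root in ("PR", "CR", "SR")}
    regulated = sorted(
        set().union(*(set(c.loc[c["call"].isin(["up", "down"]), "gene_id"]) for c in calls.values()))
    )
    profiles = ProfileMatrix(
        values=pd.DataFrame(
            {root: c.set_index("gene_id")["log2_ratio"].reindex(regulated) for root, c in calls.items()}
        )
    )
    dendro, ordered, gray = cluster_profiles(profiles)
    write_dendrogram(dendro, OUT / "cluster_merges.tsv")
    ordered.to_csv(OUT / "cluster_profiles.tsv", sep="\t")
    heights = [h for _, _, h in dendro.merges]
    print(f"{len(regulated)} regulated genes; {dendro.n_leaves} clustered, "
          f"{len(regulated) - dendro.n_leaves} gray-masked")
    print(f"merge heights {heights[0]:.3f} .. {heights[-1]:.3f} (non-decreasing: "
          f"{all(b >= a for a, b in zip(heights, heights[1:]))})")


if __name__ == "__main__":
    main()
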