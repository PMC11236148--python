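"""Beta diversity: Bray-Curtis, NMDS ordination, PERMANOVA.

On the filtered survey, habitats should separate strongly in the
ordination (low-stress configuration, small PERMANOVA p by ecosystem)
while seasons should not.
"""

from pathlib import Path

from ciliatecomm.beta import bray_curtis, nmds, permanova
from ciliatecomm.tables import read_abundance, read_metadata

SEED = 20264
OUT = Path("results")


def main() -> None:
    meta = read_metadata(OUT / "sim_filtered" / "metadata.csv")
    ab = read_abundance(OUT / "sim_filtered" / "abundance.csv", metadata=meta)
    d = bray_curtis(ab)
    d.to_frame().to_csv(OUT / "bray_curtis.tsv", sep="\t")
    ordn = nmds(d, k=2, restarts=50, seed=SEED)
    ordn.coordinates.to_csv(OUT / "nmds_coordinates.tsv", sep="\t")
    print(f"NMDS k=2: stress = {ordn.stress:.3f} "
          f"({'<' if ordn.stress < 0.3 else '>='} 0.3, "
          f"{'usable' if ordn.stress < 0.3 else 'poor'} ordination)")
    for group in ("ecosystem", "season"):
        res = permanova(d, ab.groups(group).to_numpy(), n_perm=999, seed=SEED)
        print(f"PERMANOVA by {group}: pseudo-F = {res['pseudo_F']:.2f}, p = {res['p']:.3f}")


if __name__ == "__main__":
    main()
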