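"""Scan miRNA 8mer seed sites in satellite arrays and rank the miRNAs.

Generates a major-satellite-like tandem array (234 bp units) with an 8mer
site for one miRNA family planted in every unit, then scans a small miRNA
panel against it.  Three panel members share a mature seed — as the
miR-30a/d/e-3p family does — so they receive identical counts and dominate
the ranking.
"""

from majorsat import repeats, seedscan, synthdata
from majorsat.seedscan import MiRnaRecord
from majorsat.synthdata import PlantedSite, TandemRepeatSpec

family_seed = "UUUCAGUC"  # positions 1-8 of the family's mature sequence
panel = [
    MiRnaRecord("miR-30a-3p", family_seed + "CGGGAU"),
    MiRnaRecord("miR-30d-3p", family_seed + "CGGAAU"),
    MiRnaRecord("miR-30e-3p", family_seed + "UGGUAU"),
    MiRnaRecord("miR-139-5p", "UCUACAGUGCACGUGUCUCCAGU"),
    MiRnaRecord("miR-6989-3p", "UACAGGACCUGGCUUUCAAUU"),
]

family_motif = seedscan.seed_motif(panel[0]).motif
other_motif = seedscan.seed_motif(panel[3]).motif
spec = TandemRepeatSpec(
    unit_length=234, n_units=100,
    planted_sites=(
        PlantedSite(family_motif, offset_in_unit=57),           # every unit
        PlantedSite(other_motif, offset_in_unit=120, every_k_units=5),
    ),
    rng_seed=12,
)
sequence, truth = synthdata.gen_tandem_repeat(spec)
region = repeats.SatelliteRegion("chrU_sat", 0, len(sequence), sequence=sequence)

table = seedscan.scan_regions(panel, [region], site_type="8mer", strand_mode="both")
ranked = seedscan.rank_mirnas(table, top_n=5)
print(f"array: {len(sequence):,} bp ({spec.n_units} units), "
      f"{len(truth)} planted sites\n")
print(ranked.to_string(index=False))

plus = table[(table.mirna_id == "miR-30a-3p") & (table.strand == "+")]["count"].sum()
print(f"\nThe three family members share one seed, hence one motif "
      f"({family_motif}) and identical totals; {plus} of their sites are the "
      "planted plus-strand sites (one per unit), any remainder are chance "
      "minus-strand matches. The planted-every-5-units miRNA ranks below "
      "them with 20.")
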