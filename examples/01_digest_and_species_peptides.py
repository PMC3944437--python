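"""In silico tryptic digestion and species-specific peptide classification.

Builds a miniature human/mouse ortholog pair, digests both with trypsin
rules (cleave after K/R, never before P, up to two missed cleavages), and
labels each peptide as human-specific, mouse-specific, or shared.  Shared
peptides cannot attribute a protein to tumor or stroma; species-specific
ones can.
"""

from xenomatrisome import build_digest_index, classify_species_specificity, digest
from xenomatrisome.proteomes import ProteomeEntry

human = ProteomeEntry("P_TNC_HUMAN", "human", "TNC", "GASDFGHWEKTTTAAAWGDKVLPIDEKR")
mouse = ProteomeEntry("Q_TNC_MOUSE", "mouse", "Tnc", "GASDFGHWEKTTTAASWGDKVLPLDEKR")

print("tryptic peptides of the human entry (0-2 missed cleavages):")
for pep, mc in digest(human.sequence, max_missed_cleavages=2, min_length=6, max_length=50):
    print(f"  {pep:30s} missed_cleavages={mc}")

kw = dict(max_missed_cleavages=2, min_length=6, max_length=50)
human_index = build_digest_index([human], "human", **kw)
mouse_index = build_digest_index([mouse], "mouse", **kw)

print("\nspecies specificity of the fully-cleaved peptides:")
for pep in ("GASDFGHWEK", "TTTAAAWGDK", "TTTAASWGDK", "VLPIDEK"):
    label = classify_species_specificity(pep, human_index, mouse_index)
    print(f"  {pep:15s} -> {label}")

print(
    "\nGASDFGHWEK is conserved (shared), so it cannot tell tumor from stroma;"
    "\nTTTAAAWGDK / TTTAASWGDK differ by one residue and anchor each ortholog."
    "\nVLPIDEK vs VLPLDEK differ only by I/L, which MS cannot distinguish,"
    "\nso the pair is classified as shared."
)
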