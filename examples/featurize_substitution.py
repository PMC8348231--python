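"""What the model sees: the feature vector of one substitution.

Shows the four feature categories for a leucine-to-serine change: AAindex
property deltas (mutant minus wild-type), the substitution-type one-hots,
the 23-residue neighborhood composition, and the chain length.
"""

import tempfile
from pathlib import Path

from solvar import FeatureSpace, load_aaindex, write_synthetic_aaindex
from solvar.features import neighborhood_counts, residue_group
from solvar.io import ProteinRecord, VariantRecord

work = Path(tempfile.mkdtemp())
write_synthetic_aaindex(work / "synthetic_aaindex.txt", seed=5)
space = FeatureSpace(load_aaindex(work / "synthetic_aaindex.txt"))

protein = ProteinRecord("demo", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ")
variant = VariantRecord("demo", 29, "L", "S")

vec = space.vector(protein, variant)
print(f"substitution {variant.notation} on a {len(protein)}-residue protein")
print(f"feature space: {len(vec)} named features\n")
print(f"groups: {variant.wt} is {residue_group(variant.wt)}, "
      f"{variant.mut} is {residue_group(variant.mut)}")
print(f"active substitution cells: SUB.LS={vec['SUB.LS']:.0f}, "
      f"GRP.hydrophobic.polar={vec['GRP.hydrophobic.polar']:.0f}")
window = neighborhood_counts(protein.sequence, variant.position)
print(f"neighborhood window: NonPolarAA={window['NonPolarAA']:.0f}, "
      f"PolarAA={window['PolarAA']:.0f}, ChargedAA={window['ChargedAA']:.0f} "
      f"(of {sum(window[f'AA20D.{a}'] for a in 'ACDEFGHIKLMNPQRSTVWY'):.0f} residues)")
print(f"one AAindex delta (synthetic scale FUKS010101): {vec['FUKS010101']:+.3f}")
print("\nEach substitution maps to this fixed-length vector; models never see "
      "the sequence itself, only these derived descriptors.")
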