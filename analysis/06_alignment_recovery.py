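"""Cross-replicate archetype alignment against planted identity: a k = 4
cell type over 6 donor-tissues, clean and with 30% of each marker list
scrambled. Reports adjusted Rand index, donor coverage and consensus-gene
agreement."""

import argparse

from paretocell.experiments import alignment_recovery

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

clean = alignment_recovery(noise_fraction=0.0, seed=args.seed)
noisy = alignment_recovery(noise_fraction=0.3, seed=args.seed)
print(f"zero noise: ARI {clean['ari']:.3f}, {clean['n_accepted']} accepted archetypes, "
      f"donor coverage {clean['mean_donor_coverage']:.2f}, "
      f"{clean['n_consensus_exact']} consensus lists exactly match planted markers")
print(f"30% marker noise: ARI {noisy['ari']:.3f}")
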