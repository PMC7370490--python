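"""Train an attC gHMM from annotated sites and inspect what it learned.

Uses simulator-generated training data (sequence + seven segment lengths,
the same TSV layout `cassettescan train` reads) and prints the learned
motif consensus and duration ranges.
"""

import numpy as np

from cassettescan import make_training_sites, train_model

sites = make_training_sites(n=231, seed=0, mut_rate=0.05)
model = train_model(sites, pseudocount=1.0)

print(f"trained on {len(sites)} sites\n")
for name, pwm in (("R''", model.pwm_R2), ("L''", model.pwm_L2),
                  ("L' ", model.pwm_L1), ("R' ", model.pwm_R1)):
    consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=1))
    info = [round(float(b), 1)
            for b in np.log2(4) + (pwm * np.log2(pwm)).sum(axis=1)]
    print(f"  {name} argmax consensus: {consensus}   bits/col: {info}")

for region, pmf, lo in (("spacer1", model.dur_spacer1, 1),
                        ("loop   ", model.dur_loop, 14),
                        ("spacer2", model.dur_spacer2, 1)):
    support = np.nonzero(pmf > 0)[0]
    print(f"  {region} durations: {lo + support[0]}..{lo + support[-1]} nt "
          f"(mode {lo + int(pmf.argmax())})")
print("\nThe R-box columns recover the RYYYAAC / GTTRRRY consensus; the "
      "extra-helical\nL'' column stays near-uniform, as it should for an "
      "unpaired bulge position.")
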