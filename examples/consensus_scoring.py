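"""Score citizen-science pattern categorizations by majority-vote consensus.

Simulates 31 volunteers assigning nine binary pattern categories to each
turtle, computes per-category and overall consensus proportions, and prints
the distribution summary. The worked single-category example — six '0'
votes and four '1' votes — is shown first.
"""

import numpy as np

import scutepattern as sp

votes = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1]
print(f"six 0s and four 1s -> category consensus "
      f"{sp.category_consensus(votes):.0%}\n")

# heterogeneous turtles: each with its own category probabilities
rng = np.random.default_rng(42)
frames = []
for t in range(50):
    probs = rng.uniform(0.05, 0.95, size=9)
    s = sp.generate_survey(1, 31, probs, seed=int(rng.integers(2**31)))
    s["turtle_id"] = f"t{t:03d}"
    frames.append(s)
import pandas as pd

survey = pd.concat(frames, ignore_index=True)

result = sp.consensus_table(survey)
print("per-category mean consensus across turtles:")
for cat, val in result.per_category.sort_values().items():
    print(f"  {cat:<15} {val:.2f}")
print("\noverall-consensus distribution:", {k: round(v, 3) if isinstance(v, float)
      else v for k, v in result.summary.items()})
print("\nConsensus runs from 0.5 (voters split on every category: a complex,"
      "\nhard-to-describe pattern) to 1.0 (full agreement: a simple pattern).")
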