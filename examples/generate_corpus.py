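"""Generate a small synthetic corpus and look at its shape.

The generator plants a heavy-tailed AR(1) PM2.5 series, a vocabulary of
two-character noise terms posted at a constant rate, and signal terms whose
per-post inclusion probability rises (or falls) with how unusual the day's
PM2.5 concentration is.  Roughly 10% of posts are exact duplicates, mimicking
automated posting machines.
"""

import numpy as np

from adindex import SyntheticConfig, deduplicate, generate_corpus

config = SyntheticConfig(
    n_days=60,
    posts_per_day_mean=500,
    vocab_noise_size=300,
    n_signal_pos=5,
    n_signal_neg=5,
    base_term_rate=0.01,
    seed=42,
)
posts, pm_series, truth = generate_corpus(config)
pm = np.array(list(pm_series.observations.values()))
deduped = deduplicate(posts)

print(f"posts generated:     {len(posts)} over {config.n_days} days")
print(f"after deduplication: {len(deduped)} "
      f"({100 * (len(posts) - len(deduped)) / len(posts):.1f}% removed)")
print(f"PM2.5 mean {pm.mean():.1f} ug/m3, max {pm.max():.1f} ug/m3, "
      f"days above 300: {(pm > 300).sum()}")
print(f"signal terms planted: {truth.signal_terms}")
print(f"example post text:   {posts[0].text!r}")
# The removal percentage sits near the planted 10% duplicate rate; signal
# terms are the two-character strings whose daily frequency will track PM.
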