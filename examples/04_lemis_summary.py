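"""Classify a synthetic LEMIS-style ledger: wild vs captive, seizures.

Summaries are restricted to description codes that plausibly represent
whole individuals (BOD, EGL, DEA, LIV, SPE, SKI, TRO) and weighted by
quantity.
"""

import io

import pandas as pd

from arachnotrade import filter_whole_individuals, read_lemis, summarise_lemis
from arachnotrade.synth import gen_lemis, gen_registry

records, _ = gen_registry(n_species=40, n_genera=8, seed=1)
rows, _ = gen_lemis(records, n_records=2000, seed=1)
df = read_lemis(io.StringIO(pd.DataFrame(rows).to_csv(index=False)))

whole = filter_whole_individuals(df)
summary = summarise_lemis(whole)
print(f"whole individuals: {summary['total_individuals']:.0f}")
print(f"  wild    {summary['pct_wild']:6.2f}%")
print(f"  captive {summary['pct_captive']:6.2f}%")
print(f"  other   {summary['pct_other']:6.2f}%")
print(f"  seized  {summary['pct_seized']:6.3f}%   commercial {summary['pct_commercial']:.1f}%")

top = summary["per_genus"].sort_values("total", ascending=False).head(3)
print("most-traded genera (wild fraction):")
for _, r in top.iterrows():
    print(f"  {r['genus_norm']:16s} {r['total']:9.0f} individuals, "
          f"{100 * r['wild_fraction']:.1f}% wild")

# wild + captive + other always sums to 100% of the filtered quantity: the
# source classification is an exact partition, never an estimate.
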