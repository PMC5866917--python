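"""Filter a raw hotspot list against polymorphisms and effect predictions.

Uses the packaged 12-hotspot toy fixture: 3 calls coincide with common
population variants, 2 have only benign predictions, 1 has no prediction;
6 survive both filters.
"""

from mutdomino.filters import (
    apply_deleteriousness_filter,
    filter_common_variants,
    surviving,
)
from mutdomino.simulate import toy_filter_fixture

calls, variants, predictions = toy_filter_fixture()
print(f"raw hotspot calls: {len(calls)}")

calls = filter_common_variants(calls, variants, max_freq=0.01)
common = [c for c in calls if "common_variant" in c.flags]
print(f"flagged as common variants (>1% population frequency): {len(common)}")

calls = apply_deleteriousness_filter(calls, predictions)
benign = [c for c in calls if "not_damaging" in c.flags]
unscored = [c for c in calls if "unscored" in c.flags]
print(f"flagged as not damaging: {len(benign)}; without prediction: {len(unscored)}")

kept = surviving(calls)
print(f"surviving hotspots: {len(kept)} -> "
      + ", ".join(f"{c.gene_id}:{c.residue_position}" for c in kept))
# Every input call is retained with its flag history; 'surviving' simply
# selects the calls with no exclusion flag.
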