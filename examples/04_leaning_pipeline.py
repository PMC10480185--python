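"""Hashtag-annotation table to model inputs.

Generates a synthetic annotation table (tweet/user/hashtag rows with alignment
scores in {-3,-1,0,+1,+3}), derives per-user leanings (tweet mean -> user mean
-> normalized opinion on [0,1] -> Pro/Neutral/Against label), and turns the
faction averages into a media landscape for simulations. The printed landscape
is what a 'media promoting each faction's average stance' scenario would use.
"""

import numpy as np

from bcmedia import faction_media_opinions, synthetic_annotations, user_leanings

table = synthetic_annotations(60, np.random.default_rng(1))
print(f"annotation rows: {len(table)} (users: {table.user_id.nunique()})")

records = user_leanings(table)
print(f"scorable users: {len(records)}")
print(records.head(5).to_string(index=False))
print("faction sizes:", records.label.value_counts().to_dict())

landscape = faction_media_opinions(records["opinion"], records["label"])
print("faction-average media landscape:",
      tuple(round(v, 3) for v in landscape.media_opinions))
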