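"""Build three balanced affective word lists from a norms table.

Each list holds 22 words: 6 positive, 6 negative and 6 neutral targets
framed by 4 neutral buffers, with no two consecutive targets sharing a
valence category and lists balanced on valence, arousal, length and log
frequency.  Here the norms are synthetic; swap in your own norms CSV via
recalldyn.load_norms for real stimuli.
"""

import numpy as np

from recalldyn import build_stimulus_lists, make_synthetic_norms, validate_stimulus_list
from recalldyn.data_model import CATEGORIES, norms_by_word

norms = make_synthetic_norms(seed=42)
lists = build_stimulus_lists(norms, n_lists=3, seed=7)
table = norms_by_word(norms)

for stim in lists:
    counts = {c: stim.target_count(c) for c in CATEGORIES}
    means = {
        c: np.mean([table[it.word].valence for it in stim.targets if it.category == c])
        for c in CATEGORIES
    }
    report = validate_stimulus_list(stim, norms=norms)
    print(
        f"{stim.list_id} ({stim.modality:6s}): {len(stim.items)} words, "
        f"targets {counts}, buffers {len(stim.buffers)}, "
        f"mean valence pos/neg/neu = "
        f"{means['positive']:.2f}/{means['negative']:.2f}/{means['neutral']:.2f}, "
        f"all checks passed: {report.passed}"
    )
print("\nFirst list order:", " ".join(it.word for it in lists[0].items))
print(
    "(category means sit near the nominal targets 7.5 / 2.6 / 5.18; "
    "validation confirms composition, buffer placement and ordering)"
)
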