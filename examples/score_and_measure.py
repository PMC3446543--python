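"""Score a raw recall transcript and compute the three dynamics measures.

A tiny hand-made cell shows the mechanics: the transcript is classified
event by event (targets, buffers, intrusions, repetitions), everything but
first-time target recalls is dropped, and Pstart/Pstay/Pstop are formed
from pooled counts.
"""

from recalldyn import (
    ListItem,
    ParticipantRecord,
    StimulusList,
    StudyDataset,
    pooled_pstart,
    pooled_pstay,
    pooled_pstop,
    retained_category_sequence,
    score_recall_sequence,
)

stim = StimulusList(
    "demo",
    (
        ListItem("calm", 1, "neutral", is_buffer=True),
        ListItem("misery", 2, "negative"),
        ListItem("failure", 3, "neutral"),  # neutral here for illustration
        ListItem("sunshine", 4, "positive"),
        ListItem("grief", 5, "negative"),
        ListItem("quiet", 6, "neutral", is_buffer=True),
    ),
)

transcript = ["misery", "grief", "misery", "table", "sunshine", "failure", "calm"]
seq = score_recall_sequence(transcript, stim, "p1", "T1")
for e in seq.events:
    print(f"  {e.output_position}. {e.raw_word:10s} -> {e.classification:10s} {e.category or ''}")
print("retained categories:", retained_category_sequence(seq))

data = StudyDataset((ParticipantRecord("p1", "MBCT", (seq,)),), {"demo": stim})
print("\nPstart:", {c: f"{e.numerator}/{e.denominator}" for c, e in pooled_pstart(data, "MBCT", "T1").items()})
print("Pstay :", {c: f"{e.numerator}/{e.denominator}" for c, e in pooled_pstay(data, "MBCT", "T1", ("negative", "positive")).items()})
print("Pstop :", {c: f"{e.numerator}/{e.denominator}" for c, e in pooled_pstop(data, "MBCT", "T1", ("negative", "positive")).items()})
print(
    "(the repetition of 'misery', the intrusion 'table' and the buffer "
    "'calm' are excluded; transitions jump over excluded events)"
)
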