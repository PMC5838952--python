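"""The five-category decision rule on hand-picked expression profiles.

classify_transcript needs no sequences: it takes the focal-sample TPM (Nf)
and the per-alien-sample TPMs and applies the threshold system directly
(fold X=2, over-expression Y=300 TPM, low-coverage Z=0.2 TPM by default).
"""

from crossclean import ClassifierParams, classify_transcript

profiles = [
    ("host gene, normal", 120.0, {"B": 3.0, "C": 0.5}),
    ("carried-over transcript", 2.0, {"B": 450.0, "C": 0.1}),
    ("too close to call", 8.0, {"B": 10.0, "C": 6.0}),
    ("rRNA-like, high everywhere", 2000.0, {"B": 900.0, "C": 350.0}),
    ("barely sequenced anywhere", 0.05, {"B": 0.1, "C": 0.0}),
]

for label, nf, aliens in profiles:
    call = classify_transcript(nf, aliens, ClassifierParams())
    src = f" <- {call.source_sample}" if call.source_sample else ""
    print(f"{label:28s} Nf={nf:<8g} Na={call.na:<8g} -> {call.category}{src}")

# clean: expressed far above every alien sample (Nf > 2*Na).
# cross_contamination: an alien sample expresses it >2x higher; that sample
#   is reported as the source. dubious: ratio within the 2-fold band.
# over_expressed: > 300 TPM in >= 3 samples (suspicious everywhere).
# low_coverage: < 0.2 TPM in all samples - too little signal to place it.
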