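# Surface cues that state an established drug-event relationship.
# A leading hyphen marks a suffix cue (must be attached to the preceding word).
-induced
-related
-associated
treatment-related
drug-related
due to
caused by
attributed to
associated with
secondary to
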