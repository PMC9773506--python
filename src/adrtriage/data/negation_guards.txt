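# Phrases that negate a causality cue in the same meaning unit.
no treatment-related
no drug-related
not related to
not associated with
not attributed to
without treatment-related
no deaths related
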