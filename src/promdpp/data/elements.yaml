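# Core promoter element definitions for Pol II promoters (human).
# Coordinates are TSS-relative with the TSS base at 0 (negative = upstream);
# canonical_start is the position of the consensus's first base. max_shift is
# the allowed deviation of the whole window from its canonical position.
# Consensus strings use IUPAC degenerate codes.
# Transcribed from the human core-promoter compilation of Haberle & Stark
# (2018, Nat Rev Mol Cell Biol 19:621); positions shifted by -1 from their
# +1-based TSS numbering.
elements:
  - name: BREu
    consensus: SSRCGCC
    canonical_start: -38
    max_shift: 5
    source: "TFIIB recognition element, upstream; immediately 5' of the TATA box"
  - name: TATA
    consensus: TATAWAWR
    canonical_start: -31
    max_shift: 5
    source: "TATA box, TBP binding site; spans -31..-24 (center near -27)"
  - name: BREd
    consensus: RTDKKKK
    canonical_start: -23
    max_shift: 5
    source: "TFIIB recognition element, downstream; immediately 3' of the TATA box"
  - name: Inr
    consensus: BBCABW
    canonical_start: -3
    max_shift: 5
    source: "human initiator, A at the TSS (position 0)"
  - name: DPE
    consensus: RGWYVT
    canonical_start: +27
    max_shift: 5
    source: "downstream promoter element (Drosophila consensus, as commonly applied to human)"
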