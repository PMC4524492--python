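{
 "checksums": {
  "table1.tsv": "86098f1bd6abf002c76d37de7bb0b6c3b8f33f16269bd5a112eeae2a2e8364c6",
  "tree_fig1.nwk": "1a0a3f1272890f1eed143a28a61072a31564e5cf8ca8e738ca14e09c3a9c14da",
  "core91.tsv": "1b6431bfa2e0178adcefb5bab19e2d7a2891b10f23fcf41caa475f45c50f0313",
  "ancestral_sides.tsv": "0850fdefff244f7a6255ae65c7647870d6bb6cfdacffb765998e5d45d4f26653",
  "synonyms.tsv": "1adca38019fea29cb83f4074fcabacc51703c0709a871c3b44c6317cfd84fcc9"
 },
 "notes": [
  "tree_fig1.nwk: topology transcribed from the study's reference phylogeny; nodes not corroborated by the running text are polytomies (Chlorellales backbone; Prasiola-clade backbone; Elliptochloris-clade interior; superclade backbone). Placement of Pleurastrosarcina_brevispinosa as sister to the Prasiola clade follows the figure layout and is not text-corroborated.",
  "table1.tsv: Genes/Introns(GI,GII)/Repeats(%) columns were run together in the source text; the GI/GII/repeat split for some rows was resolved using running-text constraints and remains a best-effort transcription. Genome/IR/LSC/SSC/A+T columns are unambiguous (quadripartite identity verified).",
  "table1.tsv: sizes for the three incomplete genomes (Oocystis_solitaria, Pleurastrosarcina_brevispinosa, Trebouxia_aggregata) are lower bounds; the Oocystis IR/SSC lengths are unknown (IR/SSC junction unidentified).",
  "ir_structure flags any large inverted repeat; ir_rdna flags the rDNA-encoding IR (Stichococcus_bacillaris carries an 8,272-bp IR without rRNA genes: structure=1, rdna=0)."
 ]
}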