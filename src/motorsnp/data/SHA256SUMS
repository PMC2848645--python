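e8bb6bb1bea5160ead65386db64c69703f754d32a189d09db806b7fdf1d21e7e  table1_snps.tsv
bb40c137d76cafc6aaf9cd6ac8f8d953bf59987874886bf46a2a9ab13ce0cc26  table2_myh11.tsv
06dd684fa1e6fc7b888b6fb03a6f8bad3bc6b5b2677b73a2a31c67f89dab5e7f  domain_model.json
483ceabc6a681c5338820237bca2f839a2341d50dd14388beb42ce555d1fb8ff  residue_properties.tsv
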