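iri	label	parents	keywords	dep_patterns
http://purl.obolibrary.org/obo/INO_0000002	interaction
http://purl.obolibrary.org/obo/INO_0000157	regulation	http://purl.obolibrary.org/obo/INO_0000002	control|regulates|requires|responsible
http://purl.obolibrary.org/obo/INO_0000032	regulation of transcription	http://purl.obolibrary.org/obo/INO_0000157	transcription//dependent|regulated//transcription|requires//transcription|transcription//controlling	amod(transcription, controlling)|amod(transcription, dependent)|amod(transcription, GeneX-dependent)
http://purl.obolibrary.org/obo/INO_0000038	regulation of gene expression	http://purl.obolibrary.org/obo/INO_0000157	expression//control|expression//regulated|expression//dependent|essential//expression	nsubj(control, expression)|amod(expression, dependent)|nmod(essential, expression)
http://purl.obolibrary.org/obo/INO_0000039	negative regulation of gene expression	http://purl.obolibrary.org/obo/INO_0000038	expression//negatively regulated
http://purl.obolibrary.org/obo/INO_0000040	negative regulation of transcription	http://purl.obolibrary.org/obo/INO_0000032	transcription//negatively regulated|transcription//repressor
http://purl.obolibrary.org/obo/INO_0000041	positive regulation of gene transcription	http://purl.obolibrary.org/obo/INO_0000032	transcriptional//induced|activated//transcription|transcription//induced
http://purl.obolibrary.org/obo/INO_0000042	regulation of transcription by binding to promoter	http://purl.obolibrary.org/obo/INO_0000032	binds//promoters|binds//promoter|recognized//promoter	nsubjpass(recognized, promoter)
http://purl.obolibrary.org/obo/INO_0000043	promoter-based regulation of transcription	http://purl.obolibrary.org/obo/INO_0000042	dependent//promoters|dependent//promoter//responsible//transcription
http://purl.obolibrary.org/obo/INO_0000044	regulation of protein activity	http://purl.obolibrary.org/obo/INO_0000157	inhibit//activity|inhibits//activity	dobj(inhibit, activity)
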