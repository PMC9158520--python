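# Real-accession inputs (not bundled)

The published-genome acceptance checks read GenBank flat files from this
directory, one per accession (e.g. `OM775454.gb`).  Download these
accessions from NCBI to run them:

OM775434 OM775435 OM775436 OM775437 OM775438 OM775439 OM775440 OM775441
OM775442 OM775443 OM775444 OM775445 OM775446 OM775447 OM775449 OM775450
OM775451 OM775452 OM775453 OM775454 OM775455 NC_044100

e.g.

    for acc in OM775454 OM775455 OM775438 OM775449 NC_044100; do
      curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gbwithparts&retmode=text" > ${acc}.gb
    done

The hypervariable-region check additionally needs a MAFFT whole-genome
alignment of the 22 genomes saved as `campylotropis_wga.fasta`.
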