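# Default carbon/nitrogen-cycle key-gene catalog plus stress-response markers.
# Each functional gene diagnoses one metabolic pathway; stress genes carry the
# stress category they respond to.  Fully user-replaceable: pass your own YAML
# with the same two top-level keys.
functional_genes:
  - {name: RuBisCo, cycle: carbon, pathway: CBB}
  - {name: D-glucose 6-phosphotransferase, cycle: carbon, pathway: glycolysis}
  - {name: phosphofructokinase, cycle: carbon, pathway: glycolysis}
  - {name: pyruvate dehydrogenase, cycle: carbon, pathway: TCA}
  - {name: cytochrome C oxidase, cycle: carbon, pathway: oxidative phosphorylation}
  - {name: puf operon, cycle: carbon, pathway: photoheterotrophy}
  - {name: photosystem I, cycle: carbon, pathway: photosystem I}
  - {name: photosystem II, cycle: carbon, pathway: photosystem II}
  - {name: glutamine synthetase, cycle: nitrogen, pathway: ammonia assimilation}
  - {name: nitrogenase, cycle: nitrogen, pathway: nitrogen fixation}
  - {name: nitric oxide reductase, cycle: nitrogen, pathway: denitrification}
  - {name: nitrous oxide reductase, cycle: nitrogen, pathway: denitrification}
  - {name: amoA, cycle: nitrogen, pathway: nitrification}
stress_genes:
  - {name: orange carotenoid protein, category: UV}
  - {name: photolyase, category: UV}
  - {name: superoxide dismutase, category: oxidative}
  - {name: catalase, category: oxidative}
  - {name: peroxiredoxin, category: oxidative}
  - {name: glycine betaine transporter, category: osmotic}
  - {name: trehalose synthase, category: osmotic}
  - {name: mechanosensitive channel, category: osmotic}
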