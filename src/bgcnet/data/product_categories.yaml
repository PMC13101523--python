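# Raw antiSMASH product string (lower-case) -> base biosynthetic class.
# Products absent from this table fall into "Others"; a BGC whose products
# span >= 2 distinct base classes (ignoring Others) is a hybrid.
# Lanthipeptides of every class count as RiPPs.
RiPP:
  - ripp-like
  - bacteriocin
  - lanthipeptide
  - lanthipeptide-class-i
  - lanthipeptide-class-ii
  - lanthipeptide-class-iii
  - lanthipeptide-class-iv
  - lanthipeptide-class-v
  - lantipeptide
  - lassopeptide
  - thiopeptide
  - lap
  - linaridin
  - sactipeptide
  - ranthipeptide
  - proteusin
  - microviridin
  - cyanobactin
  - thioamitides
  - lipolanthine
  - glycocin
  - bottromycin
  - epipeptide
  - fungal-ripp
  - cyclic-lactone-autoinducer
  - spliceotide
  - ripp
NRP:
  - nrps
  - nrps-like
  - nrp-metallophore
  - napaa
  - thioamide-nrp
  - cdps
  - nrp
Polyketide:
  - t1pks
  - t2pks
  - t3pks
  - transat-pks
  - transat-pks-like
  - pks-like
  - hglks
  - hgle-ks
  - pufa
  - polyketide
Terpene:
  - terpene
  - terpene-precursor
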