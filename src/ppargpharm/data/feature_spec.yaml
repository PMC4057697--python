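# Seven-feature full-agonist pharmacophore: allowed annotation-point kinds
# and pocket-arm labels per feature.  F1/F2/F4/F6 are polar (hydrogen-bond
# donor/acceptor chemistry), F3/F5/F7 hydrophobic/aromatic.
features:
  - {id: F1, kinds: [Don, Acc], arm: I}
  - {id: F2, kinds: [Acc], arm: I}
  - {id: F3, kinds: [Hyd, Aro], arm: I}
  - {id: F4, kinds: [Don, Acc], arm: II}
  - {id: F5, kinds: [Hyd, Aro], arm: II}
  - {id: F6, kinds: [Don, Acc], arm: I}
  - {id: F7, kinds: [Hyd, Aro], arm: I}
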