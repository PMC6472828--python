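prey_taxon,prey_group
shrimp,shrimp
copepod,zooplankton
euphausiid,zooplankton
mysid,zooplankton
amphipod,amphipod
capelin,fish
sand lance,fish
polychaete,polychaete
crab,crab
squid,squid
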