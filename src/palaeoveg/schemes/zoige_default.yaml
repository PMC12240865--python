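# Default taxon -> PFT -> biome scheme for the eastern Tibetan Plateau
# forest-meadow-steppe ecotone.
#
# SYNTHETIC RECONSTRUCTION: this matrix is an original recombination of
# assignments common in the Chinese biomization literature, built so that the
# packaged pipeline runs end to end. It is NOT a verbatim copy of any
# published supplementary assignment table and should be replaced by the
# user's own scheme for real reconstructions.
#
# PFT ids:
#   bec  boreal evergreen conifer        tec  temperate evergreen conifer
#   bs   boreal summergreen tree         ts   temperate summergreen tree
#   sf   steppe forb/grass               df   desert forb/shrub
#   xs   xerophytic shrub                ds   dwarf shrub
#   g    graminoid                       af   alpine/arctic forb
#   cf   cushion forb

threshold: 0.5

taxa:
  Picea: [bec]
  Abies: [bec]
  Pinus: [tec]
  Tsuga: [tec]
  Keteleeria: [tec]
  Betula: [bs]
  Corylus: [bs, ts]
  Quercus: [ts]
  Acer: [ts]
  Ulmus: [ts]
  Artemisia: [sf, df]
  Amaranthaceae: [sf, df]
  Poaceae: [sf, g]
  Ephedra: [df, xs]
  Nitraria: [df]
  Tamarix: [df]
  Zygophyllaceae: [df]
  Hippophae: [ds, xs]
  Rosaceae: [ds]
  Salix: [ds]
  Rhododendron: [ds]
  Spiraea: [ds]
  Cyperaceae: [g]
  Ranunculaceae: [af]
  Thalictrum: [af]
  Polygonum: [af]
  Asteraceae: [af]
  Gentianaceae: [af]
  Caryophyllaceae: [af, cf]
  Androsace: [cf]
  Saussurea: [af, cf]
  Leontopodium: [cf]

biomes:
  cold evergreen needle-leaved forest:
    pfts: [bec]
  cold-temperate evergreen needle-leaved and mixed forest:
    pfts: [bec, bs]
  cool evergreen needle-leaved forest:
    pfts: [bec, tec]
  cool mixed forest:
    pfts: [bec, tec, bs, ts]
  temperate deciduous broadleaved forest:
    pfts: [ts, bs]
  temperate grassland:
    pfts: [sf, g]
  temperate xerophytic shrubland:
    pfts: [xs, sf]
  erect dwarf-shrub tundra:
    pfts: [ds]
  low- and high-shrub tundra:
    pfts: [ds, xs]
  prostrate dwarf-shrub tundra:
    pfts: [ds, cf]
  graminoid and forb tundra:
    pfts: [g, af]
  cushion-forb tundra:
    pfts: [cf, af]
  desert:
    pfts: [df]

megabiomes:
  cold evergreen needle-leaved forest: forest
  cold-temperate evergreen needle-leaved and mixed forest: forest
  cool evergreen needle-leaved forest: forest
  cool mixed forest: forest
  temperate deciduous broadleaved forest: forest
  temperate grassland: steppe
  temperate xerophytic shrubland: steppe
  erect dwarf-shrub tundra: shrubland
  low- and high-shrub tundra: shrubland
  prostrate dwarf-shrub tundra: shrubland
  graminoid and forb tundra: meadow
  cushion-forb tundra: meadow
  desert: desert-steppe

# winners from these biomes are relabelled desert-steppe
desert_biomes: [desert]
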