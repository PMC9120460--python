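amber
apricot
aqua
aquamarine
azure
beige
black
blonde
blue
brass
bronze
brown
burgundy
charcoal
chartreuse
chestnut
chocolate
cinnamon
cobalt
copper
coral
cream
crimson
cyan
dark
ebony
electric
emerald
fuchsia
gold
golden
gray
green
grey
indigo
ivory
jade
khaki
lavender
lemon
lilac
lime
magenta
mahogany
maroon
mauve
metallic
mustard
ochre
olive
orange
peach
pearl
pink
platinum
plum
purple
red
rose
ruby
rust
salmon
sapphire
scarlet
sheen
silver
slate
tan
tangerine
teal
turquoise
ultramarine
vermilion
violet
white
yellow
jungle
mountain
dune
space
sea
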