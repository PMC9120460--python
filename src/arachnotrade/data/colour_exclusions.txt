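space
racing
photo
boy
bean
blaze
jungle
mountain
dune
web
colour
rainforest
tree
sea
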