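rufus
Dia
Diana
Mala
Inca
Pero
May
Janus
Yukon
Lucia
Zora
Beata
Neon
Prima
Meta
Patri
Enna
Maso
Mica
Perro
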