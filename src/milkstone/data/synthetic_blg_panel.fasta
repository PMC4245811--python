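>SYNBLG_BOS|Bos|lineage:Mammalia>Pecora>Bovidae>Bovinae>Bos
LIVTQVMKGLDIQKVAGTWYSLVMAASDISLLDAQSAPLRVYAEELKPTPEGDLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDTDYKKYLLFCMENSAEPEQSLVCQ
CLVRTPEVDDEALEKFDKALKALPMHIRLSFNPTQFEEQCHI
>SYNBLG_BUB|Bubalus|lineage:Mammalia>Pecora>Bovidae>Bovinae>Bubalus
LIVTQTMKGLDIQKVAGTWYALAMATSDISLLDAQSAPLRVYVEEFKPTPEGDLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDTDYKKYLLFCMENSAEPEQSLVCQ
CLVRTPEVDDESLEKFDKALKALPTHIRLSFNPAQLEEQCHI
>SYNBLG_OVI|Ovis|lineage:Mammalia>Pecora>Bovidae>Caprinae>Ovis
LIVTQTMKGLDIQKVAGTWYSLAMAATDISLLDAQSSPLRVYVEELKPAPEADFEILLQK
WENGECAQKKIIAEKTKIPAVFKIDSLNENKVLVLDTDYKKYLLFCMENTAEPEQSLACQ
CLVRTPEVDDESLEKFDKALKALPMHIRLSFNPTQLEEQCHI
>SYNBLG_CAP|Capra|lineage:Mammalia>Pecora>Bovidae>Caprinae>Capra
LIVTQTMKGLDIQKVAGTWYSLAMAASDISLLDTQSAPLRVYVEELKPAPEADLEIVLQK
WENGECAQKKIIAEKTKIPAVFKIDAFNENKVLALDTDYKKYLLFCMENTAEPEQSLVCQ
CVVRTPEVDDESLEKFDKALKALPMHIRLSFNPTQLEEQCHI
>SYNBLG_RAN|Rangifer|lineage:Mammalia>Pecora>Cervidae>Rangifer
LIVTQTMKGLDIQKVAGTWYSLAMSAADISLLDAQSAPLRVYVEELKPTPEGDLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDSDYKKYLLFCMENSGEPEQSLVCQ
CLVRTPEVDDESLEKFDKALKALPMHIRLSFNPVQLEEQCHI
>SYNBLG_EQU|Equus|lineage:Mammalia>Equidae>Equus
LIVSQTVKALDIQKVAGSWFSLAMAASDISLLDSQSAPLRVYVEELKPSPESDLEILLQK
WENAECSQKKIISEKTKIPATFKIDTLNENKVLVLDADFKKYLLYCMENSAEPEQALVCQ
CLVRTPETDDESLEKFDKALKALPLHIRLSYNPTQLEEQCYI
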