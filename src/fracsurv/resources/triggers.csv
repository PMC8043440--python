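phrase,kind,scope_window
kein,pre_negation,5
keine,pre_negation,5
keinen,pre_negation,5
keiner,pre_negation,5
keinem,pre_negation,5
kein nachweis,pre_negation,5
kein anhalt für,pre_negation,5
kein hinweis auf,pre_negation,5
ohne,pre_negation,5
ausschluss,pre_negation,5
ausgeschlossen,post_negation,5
nicht nachweisbar,post_negation,5
nicht abgrenzbar,post_negation,5
nicht erkennbar,post_negation,5
negiert,post_negation,5
v.a.,uncertainty,5
verdacht auf,uncertainty,5
fraglich,uncertainty,5
fragliche,uncertainty,5
fraglicher,uncertainty,5
fragliches,uncertainty,5
möglicherweise,uncertainty,5
dd,uncertainty,5
nicht sicher auszuschließen,uncertainty,5
nicht auszuschließen,uncertainty,5
empfohlen,recommendation,0
empfehlung,recommendation,0
zur weiteren abklärung,recommendation,0
ohne weiteres,pseudo_trigger,0
kein vergleich,pseudo_trigger,0
aber,termination,0
jedoch,termination,0
allerdings,termination,0
dennoch,termination,0
hingegen,termination,0
sondern,termination,0
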