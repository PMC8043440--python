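template_id,region,tags,text
aff_hw_1,hand_wrist,affirmed;easy,Distale Radiusfraktur mit Dislokation nach dorsal.
aff_hw_2,hand_wrist,affirmed;easy,Fraktur des Os scaphoideum.
aff_hw_3,hand_wrist,affirmed;easy,Basisnahe Fraktur des Metacarpale V.
aff_el_1,elbow,affirmed;easy,Dislozierte Olekranonfraktur.
aff_el_2,elbow,affirmed;easy,Radiusköpfchenfraktur mit Gelenkstufe.
aff_sh_1,shoulder,affirmed;easy,Subcapitale Humerusfraktur mit Varusfehlstellung.
aff_sh_2,shoulder,affirmed;easy,Fraktur der lateralen Klavikula.
aff_an_1,ankle,affirmed;easy,Dislozierte Weber-B-Fraktur des Außenknöchels.
aff_an_2,ankle,affirmed;easy,Außenknöchelbruch mit Verbreiterung der Syndesmose.
aff_kn_1,knee,affirmed;easy,Patellaquerfraktur mit Fragmentdiastase.
aff_kn_2,knee,affirmed;easy,Fraktur des lateralen Tibiaplateaus.
aff_ph_1,pelvis_hip,affirmed;easy,Mediale Schenkelhalsfraktur mit Varusabkippung.
aff_ph_2,pelvis_hip,affirmed;easy,Fraktur des oberen Schambeinastes.
aff_any_1,any,affirmed;easy,Frische Fraktur in typischer Lokalisation.
affhard_any_1,any,hard_affirmed;hard,Umschriebene Kortikalisunterbrechung mit diskreter Stufenbildung.
affhard_any_2,any,hard_affirmed;hard,Deutliche Stufenbildung der Kortikalis im Sinne einer frischen ossären Läsion.
neg_any_1,any,negated;easy,Kein Nachweis einer frischen Fraktur.
neg_any_2,any,negated;easy,Keine Fraktur abgrenzbar.
neg_any_3,any,negated;easy,Keine frische Fraktur oder Luxation.
neg_any_4,any,negated;easy,Fraktur ausgeschlossen.
unc_any_1,any,uncertain;easy,V.a. nicht dislozierte Fraktur
unc_any_2,any,uncertain;easy,Fragliche Fissur im Gelenkbereich
norm_any_1,any,normal;easy,Regelrechte ossäre Strukturen.
norm_any_2,any,normal;easy,Unauffällige Darstellung des Skeletts.
norm_any_3,any,normal;easy,"Regelrechte Artikulation, altersentsprechender Befund."
disb_any_1,any,distractor_blocklist;hard,Abbruch der Untersuchung bei starken Schmerzen.
disb_any_2,any,distractor_blocklist;hard,Untersuchungsabbruch auf Patientenwunsch.
disn_any_1,any,distractor_negation;hard,Die zunächst vermutete Fraktur hat sich nicht bestätigt.
disn_any_2,any,distractor_negation;hard,Alte konsolidierte Fraktur in achsgerechter Stellung.
ind_any_1,any,indication;easy,Fragestellung: Frage nach Fraktur nach Sturz.
ind_any_2,any,indication;easy,Fragestellung: Ausschluss einer Fraktur nach Trauma.
fill_any_1,any,filler;easy,Regelrechte Gelenkstellung.
fill_any_2,any,filler;easy,Keine Weichteilschwellung.
imp_aff_any_1,any,impression_affirmed;easy,Beurteilung: Fraktur wie oben beschrieben.
rec_clause_1,any,recommendation;easy,"ergänzende CT empfohlen"
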