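id,lat,lon,year,elevation_m,note
sisco,42°48′N,09°26′E,2021,25,Haute-Corse; Sisco; lower bound of the printed 25-300 m trap-line range
chioso,42.818467° N,9.434145° E,2021,225,Haute-Corse; Chioso
cognocoli-monticchi,41°51′04.4″N,08°54′00.8″E,2021,730,Corse-du-Sud; D55; Cognocoli-Monticchi
porto,42.2619,8.8291,1967,,10 km E Porto
zonza-samulaghia-1,41°45′39.6″N,9°13′37.2″E,2019,1244,Zonza; Samulaghia; marshy seep in dry Sapiniere forest
zonza-samulaghia-2,41°45′40.1″N,9°13′32.9″E,2019,1231,Zonza; Samulaghia; rocky seep at forest edge
campo-di-loro,41.93,8.79,1907,,type locality; no printed coordinates; georeferenced to the Campo dell'Oro plain near Ajaccio (gazetteer default; overridable)
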