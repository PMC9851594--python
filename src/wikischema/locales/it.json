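{
  "main_page_intro": "Questo sito è una base di dati semantica. Le pagine sono organizzate in categorie; ogni categoria ha un modulo di inserimento e una navigazione a faccette.",
  "section_build": "Costruzione e modifica della base di dati",
  "section_query": "Interrogazioni e statistiche",
  "section_export": "Esportazione",
  "add_entry": "Aggiungi una voce {category}",
  "browse": "Sfoglia {category} (drilldown)",
  "ask_page": "Componi interrogazioni semantiche (ASK)",
  "export_facts": "Esporta i dati",
  "template_doc": "Questo è il template \"{name}\". Va richiamato con un parametro per ogni proprietà.",
  "form_doc": "Questo è il modulo \"{name}\". Serve per creare o modificare pagine della categoria {name}.",
  "edit_with_form": "Crea o modifica una voce {name} con il modulo",
  "unit_suffix": "Misurata in {unit}.",
  "allowed_values": "Valori ammessi:",
  "property_of": "Proprietà della categoria {category}."
}
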