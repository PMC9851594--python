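{
  "main_page_intro": "This site is a semantic database. Pages are organised in categories; each category has an entry form and a faceted drilldown browser.",
  "section_build": "Database building and modification",
  "section_query": "Query and statistics",
  "section_export": "Export",
  "add_entry": "Add a new {category} entry",
  "browse": "Browse {category} (drilldown)",
  "ask_page": "Compose semantic (ASK) queries",
  "export_facts": "Export data",
  "template_doc": "This is the \"{name}\" template. It should be called with one named parameter per property.",
  "form_doc": "This is the \"{name}\" form. Use it to create or edit pages of category {name}.",
  "edit_with_form": "Create or edit a {name} entry with the form",
  "unit_suffix": "Measured in {unit}.",
  "allowed_values": "Allowed values:",
  "property_of": "Property of category {category}."
}
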